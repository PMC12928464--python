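import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from ugibvigil.case_processing import label_ugib
from ugibvigil.disproportionality import (
    ContingencyTable,
    MGPSPrior,
    SignalResult,
    SignalThresholds,
    bcpnn_ic,
    build_contingency,
    compute_signal,
    consensus_venn,
    ebgm,
    ebgm_many,
    evaluate_signal,
    mgps_fit,
    prr,
    ror,
    yates_chi2,
)
from ugibvigil.terms import builtin_ugib_pt_set

import oracles

cells = st.integers(min_value=1, max_value=2000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)

# prior with strictly >1 shapes so quadrature has no endpoint singularity
QUAD_PRIOR = MGPSPrior(1.4, 0.9, 3.0, 2.2, 0.35)

GRID = [
    (0, 0.5), (0, 2.0), (1, 0.5), (1, 3.0), (2, 1.0),
    (3, 0.8), (3, 6.0), (5, 5.0), (8, 2.0), (10, 10.0),
    (12, 3.0), (20, 5.0), (25, 25.0), (40, 10.0), (50, 80.0),
    (100, 30.0), (100, 100.0), (250, 120.0), (500, 480.0), (1000, 400.0),
]


class TestContingency:
    def test_toy_fixture_counts(self, toy_dataset):
        _, ids = label_ugib(toy_dataset, builtin_ugib_pt_set())
        t = build_contingency(toy_dataset, "Anticoagulin", ids)
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 5)
        assert t.N == toy_dataset.n_reports
        assert t.E == pytest.approx(4 * 3 / 10)

    def test_every_report_on_drug_empties_other_margin(self, toy_dataset):
        ds = toy_dataset.copy()
        ds.drugs["drug_name"] = "Anticoagulin"
        _, ids = label_ugib(ds, builtin_ugib_pt_set())
        t = build_contingency(ds, "Anticoagulin", ids)
        assert t.c == 0 and t.d == 0

    def test_absent_drug_warns_and_gives_zero_a(self, toy_dataset):
        with pytest.warns(UserWarning):
            t = build_contingency(toy_dataset, "Ghostmycin", {"R00"})
        assert t.a == 0
        assert t.N == toy_dataset.n_reports

    def test_event_mode_counts_reaction_rows(self, toy_dataset):
        _, ids = label_ugib(toy_dataset, builtin_ugib_pt_set())
        t = build_contingency(
            toy_dataset, "Anticoagulin", ids,
            counting_mode="event", pt_set=builtin_ugib_pt_set(),
        )
        assert t.N == len(toy_dataset.reactions)
        assert t.a == 2

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    def test_e_bounded_by_margins(self, toy_dataset):
        _, ids = label_ugib(toy_dataset, builtin_ugib_pt_set())
        t = build_contingency(toy_dataset, "Anticoagulin", ids)
        assert 0 <= t.E <= min(t.a + t.b, t.a + t.c)


class TestRorPrr:
    def test_ror_matches_woolf_oracle(self):
        t = ContingencyTable(10, 90, 100, 9900)
        got = ror(t)
        exp, lo, hi = oracles.woolf_ror(10, 90, 100, 9900)
        assert got.estimate == pytest.approx(exp, abs=1e-12)
        assert round(got.estimate, 2) == 11.00
        # frozen from the oracle: 5.5595 and 21.7645
        assert (round(got.lo, 2), round(got.hi, 2)) == (5.56, 21.76)
        assert got.lo == pytest.approx(lo, rel=1e-12)
        assert got.hi == pytest.approx(hi, rel=1e-12)

    def test_prr_matches_hand_arithmetic(self):
        got = prr(ContingencyTable(10, 90, 100, 9900))
        assert got.estimate == pytest.approx(10.0)
        e, lo, hi = oracles.evans_prr(10, 90, 100, 9900)
        assert (got.lo, got.hi) == (pytest.approx(lo), pytest.approx(hi))

    def test_balanced_table_is_null(self):
        t = ContingencyTable(5, 5, 5, 5)
        assert ror(t).estimate == pytest.approx(1.0)
        assert prr(t).estimate == pytest.approx(1.0)
        assert prr(t).chi2 == 0.0  # Yates correction floors at zero

    @given(tables)
    def test_cross_product_identity_gives_unit_ror(self, t):
        scaled = ContingencyTable(t.a * t.c, t.a * t.d, t.b * t.c, t.b * t.d)
        assert ror(scaled).estimate == pytest.approx(1.0)

    @given(tables)
    def test_ror_dominates_prr_on_the_same_side_of_one(self, t):
        r, p = ror(t).estimate, prr(t).estimate
        if r > 1:
            assert r >= p - 1e-12
        elif r < 1:
            assert r <= p + 1e-12

    @given(tables)
    def test_interval_ordering(self, t):
        r, p = ror(t), prr(t)
        assert r.lo <= r.estimate <= r.hi
        assert p.lo <= p.estimate <= p.hi
        ic = bcpnn_ic(t)
        assert ic.ic025 <= ic.ic + 1e-12

    @given(tables)
    def test_yates_chi2_matches_scipy(self, t):
        ours = yates_chi2(t)
        ref = sps.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=True
        ).statistic
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_monotone_in_a_with_other_cells_fixed(self):
        prior = QUAD_PRIOR
        last = (0.0, 0.0, 0.0, -math.inf)
        for a in (1, 3, 9, 27, 81):
            t = ContingencyTable(a, 50, 40, 900)
            vals = (
                ror(t).estimate,
                prr(t).estimate,
                ebgm(t, prior).ebgm,
                bcpnn_ic(t).ic,
            )
            assert all(v > l for v, l in zip(vals, last))
            last = vals

    def test_zero_cell_uses_haldane_correction(self):
        t = ContingencyTable(0, 10, 10, 100)
        got = ror(t)
        assert got.corrected
        assert got.estimate == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))

    def test_zero_cell_without_correction_is_nan_sentinel(self):
        got = ror(ContingencyTable(0, 10, 10, 100), zero_correction=False)
        assert math.isnan(got.estimate) and math.isnan(got.lo)


class TestBcpnn:
    def test_standard_point_is_shrunk_log_ratio(self):
        t = ContingencyTable(100, 900, 1000, 99000)
        got = bcpnn_ic(t)
        assert got.ic == pytest.approx(math.log2((100 + 0.5) / (t.E + 0.5)))

    @pytest.mark.parametrize("a,e", GRID)
    def test_ic025_matches_quadrature_oracle(self, a, e):
        from types import SimpleNamespace

        table = SimpleNamespace(a=a, E=e)  # bcpnn_ic only reads a and E
        got = bcpnn_ic(table)
        q = oracles.gamma_quantile_quad(a + 0.5, e + 0.5, 0.025)
        assert got.ic == pytest.approx(math.log2((a + 0.5) / (e + 0.5)))
        assert got.ic025 == pytest.approx(math.log2(q), abs=1e-6)

    def test_paper_compat_reproduces_printed_ic(self):
        t = ContingencyTable(1, 1, 1, 1)
        assert bcpnn_ic(t, "paper_compat", ebgm_value=32.24).ic == pytest.approx(
            5.01, abs=5e-3
        )
        assert bcpnn_ic(t, "paper_compat", ebgm_value=1.0).ic == 0.0

    def test_paper_compat_interval_is_fixed_offset(self):
        t = ContingencyTable(1, 1, 1, 1)
        got = bcpnn_ic(t, "paper_compat", ebgm_value=16.08)
        assert got.ic - got.ic025 == pytest.approx(1.67)


class TestEbgm:
    def test_large_count_consistency(self):
        got = ebgm(1000, QUAD_PRIOR, e=100.0)
        assert got.ebgm == pytest.approx(10.0, rel=0.02)
        assert got.ebgm05 < got.ebgm

    def test_no_data_limit_returns_prior_geometric_mean(self):
        from scipy import special

        got = ebgm(0, QUAD_PRIOR, e=1e-9)
        p = QUAD_PRIOR
        prior_gm = math.exp(
            p.w * (special.digamma(p.alpha1) - math.log(p.beta1))
            + (1 - p.w) * (special.digamma(p.alpha2) - math.log(p.beta2))
        )
        assert got.ebgm == pytest.approx(prior_gm, rel=1e-6)

    @pytest.mark.parametrize("a,e", GRID)
    def test_matches_quadrature_oracle(self, a, e):
        point, q05 = ebgm(a, QUAD_PRIOR, e=e)
        o_point, o_q05 = oracles.ebgm_quadrature(QUAD_PRIOR, a, e)
        assert point == pytest.approx(o_point, rel=1e-6)
        assert q05 == pytest.approx(o_q05, rel=1e-6)

    def test_vectorized_matches_scalar(self):
        a = np.array([0, 3, 10])
        e = np.array([1.0, 2.0, 5.0])
        pts, q05s = ebgm_many(a, e, QUAD_PRIOR)
        for i in range(3):
            s = ebgm(int(a[i]), QUAD_PRIOR, e=float(e[i]))
            assert pts[i] == pytest.approx(s.ebgm)
            assert q05s[i] == pytest.approx(s.ebgm05)


class TestMgpsFit:
    def test_null_poisson_data_centers_prior_near_one(self):
        rng = np.random.default_rng(1)
        e = rng.lognormal(mean=2.0, sigma=1.0, size=4000)
        a = rng.poisson(e)
        prior = mgps_fit(a, e)
        pts, _ = ebgm_many(a[:500], e[:500], prior)
        assert 0.8 <= np.median(pts) <= 1.2

    def test_recovers_ebgm_functional_from_known_prior(self):
        truth = MGPSPrior(0.5, 0.5, 3.0, 3.0, 0.4)
        rng = np.random.default_rng(2)
        n = 5000
        e = rng.lognormal(mean=1.5, sigma=1.2, size=n)
        comp = rng.random(n) < truth.w
        lam = np.where(
            comp,
            rng.gamma(truth.alpha1, 1 / truth.beta1, n),
            rng.gamma(truth.alpha2, 1 / truth.beta2, n),
        )
        a = rng.poisson(lam * e)
        fitted = mgps_fit(a, e)
        assert fitted.source == "fitted"
        idx = rng.choice(n, 400, replace=False)
        got, _ = ebgm_many(a[idx], e[idx], fitted)
        want, _ = ebgm_many(a[idx], e[idx], truth)
        rel = np.abs(got - want) / want
        assert np.median(rel) <= 0.05

    def test_single_component_reduces_to_plain_gamma_poisson(self):
        rng = np.random.default_rng(3)
        e = rng.lognormal(1.0, 1.0, 2000)
        lam = rng.gamma(2.0, 1 / 2.0, 2000)
        a = rng.poisson(lam * e)
        prior = mgps_fit(a, e, single_component=True)
        assert prior.w == 1.0
        assert (prior.alpha1, prior.beta1) == (prior.alpha2, prior.beta2)
        assert prior.alpha1 == pytest.approx(2.0, rel=0.25)

    def test_too_few_pairs_falls_back(self):
        prior = mgps_fit([1, 2, 3], [1.0, 1.0, 1.0])
        assert prior.source == "fallback"
        assert prior.w == 1.0


class TestFlagsAndConsensus:
    def _result(self, **over):
        base = dict(
            drug="X", a=100, ror=3.0, ror_lo=2.5, ror_hi=3.6, prr=2.9,
            prr_lo=2.4, prr_hi=3.5, chi2=50.0, ic=1.5, ic025=1.0,
            ebgm=2.8, ebgm05=2.4,
        )
        base.update(over)
        return SignalResult(**base)

    def test_count_floor_blanks_all_flags(self):
        res = evaluate_signal(self._result(a=2))
        assert res.flag_all_four is False
        assert not any(
            (res.flag_ror, res.flag_prr, res.flag_ebgm, res.flag_bcpnn)
        )

    def test_protective_ror_not_flagged(self):
        # an inverse-association profile: ROR 0.51 (0.48-0.55)
        res = evaluate_signal(
            self._result(ror=0.51, ror_lo=0.48, ror_hi=0.55, prr=0.51,
                         ic025=-2.61, ebgm05=0.49)
        )
        assert res.flag_ror is False
        assert res.flag_all_four is False

    def test_strong_signal_flags_all_four(self):
        res = evaluate_signal(self._result())
        assert res.flag_all_four is True

    @given(
        st.integers(0, 50),
        st.floats(0.1, 10),
        st.floats(0.0, 100),
        st.floats(-3, 3),
        st.floats(0.1, 10),
    )
    def test_flags_equal_bruteforce_rule_evaluation(self, a, prr_v, chi2, ic025, eb05):
        thresholds = SignalThresholds()
        res = evaluate_signal(
            self._result(a=a, prr=prr_v, chi2=chi2, ic025=ic025, ebgm05=eb05,
                         ror_lo=prr_v * 0.8)
        )
        if a < 3:
            want = (False, False, False, False)
        else:
            want = (
                prr_v * 0.8 > 1.0,
                prr_v >= 2.0 and chi2 >= 4.0,
                eb05 > 2.0,
                ic025 > 0.0,
            )
        assert (res.flag_ror, res.flag_prr, res.flag_ebgm, res.flag_bcpnn) == want

    def test_venn_enumeration(self):
        all_four = evaluate_signal(self._result(drug="A"))
        ror_only = evaluate_signal(
            self._result(drug="B", prr=1.0, ic025=-1.0, ebgm05=1.0)
        )
        none = evaluate_signal(
            self._result(drug="C", ror_lo=0.5, prr=1.0, ic025=-1.0, ebgm05=1.0)
        )
        venn = consensus_venn([all_four, ror_only, none])
        assert venn["ROR+PRR+EBGM+BCPNN"] == 1
        assert venn["ROR"] == 1
        assert venn["none"] == 1
        assert sum(venn.values()) == 3

    @given(st.lists(st.sets(st.sampled_from(["ROR", "PRR", "EBGM", "BCPNN"])),
                    min_size=1, max_size=25))
    def test_venn_matches_power_set_oracle(self, flag_sets):
        results = []
        for i, flags in enumerate(flag_sets):
            results.append(
                self._result(
                    drug=f"D{i}",
                    ror_lo=2.0 if "ROR" in flags else 0.5,
                    prr=3.0 if "PRR" in flags else 1.0,
                    chi2=50.0 if "PRR" in flags else 0.0,
                    ebgm05=3.0 if "EBGM" in flags else 1.0,
                    ic025=1.0 if "BCPNN" in flags else -1.0,
                )
            )
        results = [evaluate_signal(r) for r in results]
        venn = consensus_venn(results)
        assert venn == oracles.region_counts_bruteforce(flag_sets)
        positives = sum(1 for f in flag_sets if f)
        assert sum(v for k, v in venn.items() if k != "none") == positives


class TestComputeSignal:
    def test_compat_mode_identities_hold_exactly(self):
        t = ContingencyTable(50, 450, 500, 49500)
        res = compute_signal("X", t, QUAD_PRIOR, ic_mode="paper_compat")
        assert res.ic == math.log2(res.ebgm)
        assert res.ic025 == res.ic - 1.67

    def test_threshold_config_file_round_trip(self, tmp_path):
        path = tmp_path / "thresholds.txt"
        path.write_text("min_a = 5\nebgm05_min = 1.5  # relaxed\n")
        th = SignalThresholds.from_file(path)
        assert th.min_a == 5 and th.ebgm05_min == 1.5
        assert th.prr_min == 2.0  # untouched default
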