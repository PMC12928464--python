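"""The built-in MedDRA Preferred Term set for upper-GI bleeding (UGIB).

The event definition starts from the standardized MedDRA query
"Gastrointestinal Haemorrhage" (SMQ 2000018) narrowed by anatomical
location to sites between the oral cavity and the ligament of Treitz,
which yields 17 Preferred Terms.  Terms that do not localize the
bleeding source (e.g. Melaena) are excluded.

Arbitrary user-supplied PT sets are accepted everywhere a PT set is
needed; this module only bakes in the UGIB default.
"""

from __future__ import annotations

from typing import Iterable

PTPair = tuple[int, str]

_UGIB_PTS: tuple[PTPair, ...] = (
    (10013839, "Duodenal ulcer haemorrhage"),
    (10013865, "Duodenitis haemorrhagic"),
    (10017788, "Gastric haemorrhage"),
    (10067855, "Gastric occult blood positive"),
    (10017826, "Gastric ulcer haemorrhage"),
    (10017829, "Gastric ulcer haemorrhage, obstructive"),
    (10017866, "Gastritis haemorrhagic"),
    (10053768, "Gastroduodenal haemorrhage"),
    (10018830, "Haematemesis"),
    (10067786, "Haemorrhagic erosive gastritis"),
    (10026712, "Mallory-Weiss syndrome"),
    (10030172, "Oesophageal haemorrhage"),
    (10030202, "Oesophageal ulcer haemorrhage"),
    (10030219, "Oesophagitis haemorrhagic"),
    (10034344, "Peptic ulcer haemorrhage"),
    (10085612, "Stress ulcer haemorrhage"),
    (10046274, "Upper gastrointestinal haemorrhage"),
)


def builtin_ugib_pt_set() -> set[PTPair]:
    """Return the 17 (code, name) UGIB Preferred Term pairs."""
    return set(_UGIB_PTS)


def pt_codes(pt_set: Iterable[PTPair]) -> set[int]:
    return {code for code, _ in pt_set}


def pt_names_lower(pt_set: Iterable[PTPair]) -> set[str]:
    """Lower-cased names, for case-insensitive matching against verbatim text."""
    return {name.lower() for _, name in pt_set}
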