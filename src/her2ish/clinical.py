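"""Bundled de-identified clinical reference cases.

Ten invasive breast carcinoma cases with their manual fluorescence-ISH
quantities (the reference assay): HER2/CEP17 ratio, mean HER2 and CEP17
signals per nucleus, the resulting ASCO/CAP ISH group, and the binary
amplification call.  They serve as golden inputs for the scoring rules and as
anchors for realistic simulation profiles.

Case 6 has no FISH quantities (IHC score 3+, reported amplified / group 1
directly); its numeric fields are ``None``.  For a subset of cases the printed
ratio equals the 2-decimal rounding of the quotient of the printed means;
:data:`SELF_CONSISTENT_CASE_IDS` lists them.  The remaining cases carry small
rounding inconsistencies in their source values (e.g. case 7: 7.18/1.8 = 3.99
vs the printed 3.89) and are used as printed, without forcing consistency.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ClinicalCase:
    case_id: int
    fish_ratio: float | None
    her2_per_nucleus: float | None
    cep17_per_nucleus: float | None
    ish_group: int
    amplified: bool


REFERENCE_CASES: tuple[ClinicalCase, ...] = (
    ClinicalCase(1, 1.41, 3.82, 2.7, 5, False),
    ClinicalCase(2, 1.31, 2.36, 1.8, 5, False),
    ClinicalCase(3, 1.14, 2.62, 2.3, 5, False),
    ClinicalCase(4, 1.48, 4.11, 2.8, 4, False),
    ClinicalCase(5, 1.73, 4.64, 2.7, 4, False),
    ClinicalCase(6, None, None, None, 1, True),
    ClinicalCase(7, 3.89, 7.18, 1.8, 1, True),
    ClinicalCase(8, 2.65, 7.2, 2.7, 1, True),
    ClinicalCase(9, 2.49, 11.19, 4.5, 1, True),
    ClinicalCase(10, 8.88, 18.65, 2.1, 1, True),
)

#: Cases whose printed ratio equals round(HER2/CEP17, 2) of the printed means.
SELF_CONSISTENT_CASE_IDS: tuple[int, ...] = (1, 2, 3, 9, 10)


def cases_with_fish() -> list[ClinicalCase]:
    """The nine cases carrying numeric FISH quantities."""
    return [c for c in REFERENCE_CASES if c.fish_ratio is not None]
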