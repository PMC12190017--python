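"""ASCO/CAP scoring of per-nucleus dual-probe ISH counts.

This module is the quantification core of the pipeline.  Given nuclei whose
HER2 and CEP17 (chromosome-17 centromere) signal counts have been filled in,
it applies the nucleus inclusion rule (by default a nucleus must carry at
least two signals of each probe, i.e. possess two complete chromosomes 17),
averages the first 20-200 reportable nuclei, and classifies the case into one
of the five ASCO/CAP ISH groups:

======  ======================  =========================
group   HER2/CEP17 ratio        mean HER2 copies per cell
======  ======================  =========================
1       >= 2.0                  >= 4.0
2       >= 2.0                  <  4.0
3       <  2.0                  >= 6.0
4       <  2.0                  >= 4.0 and < 6.0
5       <  2.0                  <  4.0
======  ======================  =========================

HER2 status is *Amplified* exactly when the case falls in group 1.  The five
regions partition the non-negative (ratio, copies) quadrant; boundaries are
inclusive (``>=``) as written above.

Nucleus objects are duck-typed: anything with ``her2_count``, ``cep17_count``,
``edge_touching``, ``area_um2``, ``roi_id`` and ``label`` attributes works
(see :class:`her2ish.segment.NucleusRecord`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

AMPLIFIED = "Amplified"
NON_AMPLIFIED = "Non-amplified"

#: Reportable-nucleus count limits of the reporting rule.
MIN_REPORTED = 20
MAX_REPORTED = 200

#: Half-width of the ratio band around 2.0 treated as borderline.
BORDERLINE_RATIO_BAND = (1.8, 2.2)


@dataclass(frozen=True)
class InclusionPolicy:
    """Minimum per-nucleus signal counts for a nucleus to be reportable.

    The defaults (2, 2) select nuclei possessing two complete chromosomes 17.
    ``aneusomy_mode`` marks policies whose minima were relaxed for monosomy /
    polysomy work-ups; it is carried into reports but the filter always uses
    the explicit minima.
    """

    min_her2: int = 2
    min_cep17: int = 2
    aneusomy_mode: bool = False
    name: str = "standard"

    def __post_init__(self) -> None:
        if self.min_her2 < 0 or self.min_cep17 < 0:
            raise ValueError("inclusion minima must be >= 0")


DEFAULT_POLICY = InclusionPolicy()
#: Fully relaxed minima for aneusomy analyses.
ANEUSOMY_POLICY = InclusionPolicy(1, 1, aneusomy_mode=True, name="aneusomy")
#: Relaxed CEP17 minimum for chromosome-17 monosomy cases.
MONOSOMY_POLICY = InclusionPolicy(2, 1, aneusomy_mode=True, name="monosomy")
#: Alias: polysomy cases keep the standard minima (counts are high, not low).
POLYSOMY_POLICY = InclusionPolicy(2, 2, aneusomy_mode=True, name="polysomy")


@dataclass(frozen=True)
class QuantResult:
    """Case-level quantification outcome.

    ``ish_group`` / ``status`` / ``borderline`` are ``None`` until
    :func:`finalize` is applied (or when the case is insufficient, mirroring
    the "n/a" outcome of an unanalyzable slide).
    """

    n_reported: int
    mean_her2_per_cell: float
    mean_cep17_per_cell: float
    ratio: float
    ish_group: int | None = None
    status: str | None = None
    borderline: bool | None = None
    insufficient: bool = False

    def rounded(self, ndigits: int = 2) -> dict:
        """Display form with means/ratio rounded (classification never uses
        rounded values)."""
        return {
            "n_reported": self.n_reported,
            "mean_her2_per_cell": round(self.mean_her2_per_cell, ndigits),
            "mean_cep17_per_cell": round(self.mean_cep17_per_cell, ndigits),
            "ratio": round(self.ratio, ndigits) if math.isfinite(self.ratio) else None,
            "ish_group": self.ish_group,
            "status": self.status,
            "borderline": self.borderline,
            "insufficient": self.insufficient,
        }


def filter_reportable(nuclei: Iterable, policy: InclusionPolicy = DEFAULT_POLICY) -> list:
    """Keep nuclei meeting the policy minima and not touching the ROI edge.

    Input order is preserved.  Kept records get ``reportable = True`` when the
    attribute exists and is writable.
    """
    kept = [
        n
        for n in nuclei
        if n.her2_count >= policy.min_her2
        and n.cep17_count >= policy.min_cep17
        and not getattr(n, "edge_touching", False)
    ]
    for n in kept:
        try:
            n.reportable = True
        except AttributeError:  # frozen stand-ins in tests
            pass
    return kept


def _report_order_key(n) -> tuple:
    # Deterministic "first n" selection: largest nuclei first, ties broken by
    # provenance (ROI id, then label).
    return (-float(getattr(n, "area_um2", 0.0) or 0.0), str(getattr(n, "roi_id", "")), int(getattr(n, "label", 0)))


def quantify(nuclei: Sequence, n_to_report: int = MIN_REPORTED) -> QuantResult:
    """Average the first ``min(n_to_report, available)`` reportable nuclei.

    Nuclei are taken in a deterministic order (descending area, then ROI id
    and label).  Means are arithmetic; ``ratio = mean_her2 / mean_cep17``.
    Fewer than 20 available nuclei flags the result as insufficient.
    """
    if not MIN_REPORTED <= n_to_report <= MAX_REPORTED:
        raise ValueError(f"n_to_report must be in [{MIN_REPORTED}, {MAX_REPORTED}], got {n_to_report}")
    chosen = sorted(nuclei, key=_report_order_key)[: int(n_to_report)]
    k = len(chosen)
    if k == 0:
        return QuantResult(0, float("nan"), float("nan"), float("nan"), insufficient=True)
    mean_h = sum(n.her2_count for n in chosen) / k
    mean_c = sum(n.cep17_count for n in chosen) / k
    ratio = mean_h / mean_c if mean_c > 0 else float("nan")
    return QuantResult(k, mean_h, mean_c, ratio, insufficient=k < MIN_REPORTED)


def _check_pair(ratio: float, mean_her2_per_cell: float) -> None:
    if math.isnan(ratio) or math.isnan(mean_her2_per_cell):
        raise ValueError("ratio and mean HER2 copies must not be NaN")
    if ratio < 0 or mean_her2_per_cell < 0:
        raise ValueError("ratio and mean HER2 copies must be >= 0")


def classify_ish_group(ratio: float, mean_her2_per_cell: float) -> int:
    """ASCO/CAP ISH group (1-5) for a HER2/CEP17 ratio and mean HER2 copies.

    Boundaries are inclusive: (2.0, 4.0) is group 1.
    """
    _check_pair(ratio, mean_her2_per_cell)
    if ratio >= 2.0:
        return 1 if mean_her2_per_cell >= 4.0 else 2
    if mean_her2_per_cell >= 6.0:
        return 3
    if mean_her2_per_cell >= 4.0:
        return 4
    return 5


def her2_status(ratio: float, mean_her2_per_cell: float) -> str:
    """``Amplified`` iff ratio >= 2.0 and mean HER2 copies >= 4.0 (group 1)."""
    _check_pair(ratio, mean_her2_per_cell)
    if ratio >= 2.0 and mean_her2_per_cell >= 4.0:
        return AMPLIFIED
    return NON_AMPLIFIED


def is_borderline(result: QuantResult) -> bool:
    """Whether the case warrants the extended 40-nucleus count.

    True for ISH groups 2-4 (the guideline's equivocal work-up groups) or a
    ratio within the historical equivocal band [1.8, 2.2].
    """
    if result.ish_group is None:
        raise ValueError("is_borderline requires a classified result (group set)")
    lo, hi = BORDERLINE_RATIO_BAND
    in_band = math.isfinite(result.ratio) and lo <= result.ratio <= hi
    return result.ish_group in (2, 3, 4) or in_band


def finalize(result: QuantResult) -> QuantResult:
    """Attach group, status and borderline flag to a quantified result.

    Insufficient results (or results with an undefined ratio) stay
    unclassified -- the "n/a" outcome.
    """
    if result.insufficient or not math.isfinite(result.ratio):
        return result
    group = classify_ish_group(result.ratio, result.mean_her2_per_cell)
    status = her2_status(result.ratio, result.mean_her2_per_cell)
    out = replace(result, ish_group=group, status=status)
    return replace(out, borderline=is_borderline(out))
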