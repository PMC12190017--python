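"""ROI annotations and the case-level accretion workflow.

A pathologist selects one or two regions of interest (0.1-0.3 mm^2) and adds
more until the pipeline has found the required number of reportable nuclei:
20 for regular cases, 40 for borderline ones.  :func:`accrete_rois` processes
ROIs in annotation priority order, pools reportable nuclei, and stops at the
first ROI after which the pool meets the requirement.  :func:`run_case` wraps
the whole case workflow: accrete to 20, quantify and classify, and -- when
the result is borderline -- re-accrete to 40 and re-quantify before the final
classification.  If an initial pass suggests chromosome-17 monosomy (most
nuclei carrying fewer than two CEP17 signals), the inclusion policy is
relaxed to the monosomy preset and accretion restarts, mirroring the
adjustable-threshold work-up for aneusomy cases.

ROI size is tracked as uncompressed RGB megabytes (width x height x 3 / 1e6),
a deterministic, format-independent stand-in for viewer-reported file size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from shapely.geometry import Polygon, box, mapping, shape

from .scoring import (
    DEFAULT_POLICY,
    MONOSOMY_POLICY,
    InclusionPolicy,
    QuantResult,
    filter_reportable,
    finalize,
    quantify,
)
from .segment import NucleusRecord

CASE_REPORT_SCHEMA = "her2ish/case-report-1"
ROI_GEOJSON_SCHEMA = "her2ish/rois-geojson-1"

#: Fraction of candidate nuclei below two CEP17 signals that triggers the
#: monosomy work-up (relaxed CEP17 minimum).
MONOSOMY_REFLEX_FRACTION = 0.6


@dataclass(frozen=True)
class RoiAnnotation:
    """A polygonal ROI in slide coordinates (micrometres).

    ``pixel_bbox`` is the half-open pixel box covering the polygon at the
    annotation's resolution; ``size_mb`` is its uncompressed RGB footprint.
    """

    id: str
    polygon: Polygon
    resolution_um_per_px: float
    kind: str = "analysis"

    def __post_init__(self) -> None:
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution must be positive")
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise ValueError(f"ROI {self.id}: polygon must be simple and valid")
        if self.polygon.area <= 0:
            raise ValueError(f"ROI {self.id}: polygon area must be positive")

    @property
    def pixel_bbox(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) half-open pixel box at the ROI resolution."""
        minx, miny, maxx, maxy = self.polygon.bounds
        res = self.resolution_um_per_px
        return (
            int(math.floor(minx / res)),
            int(math.floor(miny / res)),
            int(math.ceil(maxx / res)),
            int(math.ceil(maxy / res)),
        )

    @property
    def size_mb(self) -> float:
        x0, y0, x1, y1 = self.pixel_bbox
        return (x1 - x0) * (y1 - y0) * 3 / 1e6

    def with_resolution(self, resolution_um_per_px: float) -> "RoiAnnotation":
        """Clone this annotation into another scan's coordinate frame (the
        polygon lives in slide micrometres, so only the resolution changes)."""
        return RoiAnnotation(self.id, self.polygon, resolution_um_per_px, self.kind)


def rectangle_roi(
    roi_id: str, x_um: float, y_um: float, width_um: float, height_um: float,
    resolution_um_per_px: float, kind: str = "analysis",
) -> RoiAnnotation:
    return RoiAnnotation(
        roi_id, box(x_um, y_um, x_um + width_um, y_um + height_um), resolution_um_per_px, kind
    )


def rois_to_geojson(rois: Sequence[RoiAnnotation], path: str | Path | None = None) -> dict:
    fc = {
        "type": "FeatureCollection",
        "schema": ROI_GEOJSON_SCHEMA,
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(r.polygon),
                "properties": {
                    "id": r.id,
                    "kind": r.kind,
                    "resolution_um_per_px": r.resolution_um_per_px,
                },
            }
            for r in rois
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc


def rois_from_geojson(source: str | Path) -> list[RoiAnnotation]:
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    data = json.loads(text)
    schema = data.get("schema", ROI_GEOJSON_SCHEMA)
    if not schema.startswith("her2ish/rois-geojson-"):
        raise ValueError(f"not an ROI document: {schema!r}")
    if int(schema.rsplit("-", 1)[1]) > 1:
        raise ValueError(f"ROI schema {schema!r} is newer than this reader")
    rois = []
    for feat in data["features"]:
        props = feat.get("properties", {})
        rois.append(
            RoiAnnotation(
                id=str(props["id"]),
                polygon=shape(feat["geometry"]),
                resolution_um_per_px=float(props["resolution_um_per_px"]),
                kind=props.get("kind", "analysis"),
            )
        )
    return rois


def check_non_overlapping(rois: Sequence[RoiAnnotation]) -> None:
    """Reject overlapping ROI pairs (nuclei must not be counted twice)."""
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            inter = rois[i].polygon.intersection(rois[j].polygon)
            if inter.area > 1e-9:
                raise ValueError(f"ROIs {rois[i].id!r} and {rois[j].id!r} overlap")


@dataclass
class AccretionResult:
    used_rois: list[RoiAnnotation]
    all_nuclei: list[NucleusRecord]
    reportable: list[NucleusRecord]
    per_roi_counts: dict[str, tuple[int, int]]  # roi id -> (detected, reportable)
    insufficient: bool

    @property
    def total_size_mb(self) -> float:
        return sum(r.size_mb for r in self.used_rois)


def accrete_rois(
    rois: Sequence[RoiAnnotation],
    analyze_fn: Callable[[RoiAnnotation], list[NucleusRecord]],
    policy: InclusionPolicy,
    n_required: int,
) -> AccretionResult:
    """Add ROIs in priority order until enough reportable nuclei are pooled.

    Stops at the first ROI after which the pooled reportable count reaches
    ``n_required`` (20 regular / 40 borderline); ROIs after the stopping
    point are never analyzed.  Runs out below 20 -> flagged insufficient.
    """
    if n_required not in (20, 40):
        raise ValueError("n_required must be 20 or 40")
    check_non_overlapping(rois)
    used: list[RoiAnnotation] = []
    pooled: list[NucleusRecord] = []
    reportable: list[NucleusRecord] = []
    per_roi: dict[str, tuple[int, int]] = {}
    for roi in rois:
        nuclei = analyze_fn(roi)
        rep = filter_reportable(nuclei, policy)
        used.append(roi)
        pooled.extend(nuclei)
        reportable.extend(rep)
        per_roi[roi.id] = (len(nuclei), len(rep))
        if len(reportable) >= n_required:
            break
    return AccretionResult(
        used_rois=used,
        all_nuclei=pooled,
        reportable=reportable,
        per_roi_counts=per_roi,
        insufficient=len(reportable) < 20,
    )


def nuclei_per_mb(n_nuclei: int, used_rois: Sequence[RoiAnnotation]) -> float:
    """Detected nuclei per megabyte of consumed ROI area."""
    total = sum(r.size_mb for r in used_rois)
    if total <= 0:
        raise ValueError("total ROI size must be positive")
    return n_nuclei / total


@dataclass
class CaseReport:
    """Case-level outcome plus full provenance for bit-identical re-derivation."""

    case_id: str
    result: QuantResult
    analyzable: bool
    policy: InclusionPolicy
    n_required: int
    used_roi_ids: list[str]
    per_roi_counts: dict[str, tuple[int, int]]
    detected_nuclei: int
    size_mb_used: float
    nuclei_per_mb: float
    borderline_pass: bool
    monosomy_reflex: bool
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema": CASE_REPORT_SCHEMA,
            "case_id": self.case_id,
            "analyzable": self.analyzable,
            "result": self.result.rounded(),
            "policy": {
                "name": self.policy.name,
                "min_her2": self.policy.min_her2,
                "min_cep17": self.policy.min_cep17,
                "aneusomy_mode": self.policy.aneusomy_mode,
            },
            "n_required": self.n_required,
            "used_roi_ids": self.used_roi_ids,
            "per_roi_counts": {k: list(v) for k, v in self.per_roi_counts.items()},
            "detected_nuclei": self.detected_nuclei,
            "size_mb_used": round(self.size_mb_used, 6),
            "nuclei_per_mb": round(self.nuclei_per_mb, 4),
            "borderline_pass": self.borderline_pass,
            "monosomy_reflex": self.monosomy_reflex,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_case(
    rois: Sequence[RoiAnnotation],
    analyze_fn: Callable[[RoiAnnotation], list[NucleusRecord]],
    policy: InclusionPolicy = DEFAULT_POLICY,
    case_id: str = "case",
    monosomy_reflex: bool = True,
    provenance: dict | None = None,
) -> CaseReport:
    """Full case workflow: accrete, quantify, classify, extend if borderline.

    ``analyze_fn`` maps one ROI to its nucleus records (with counts filled);
    it is called at most once per ROI (results are cached), so re-filtering
    under a relaxed policy or the borderline extension never re-analyzes.
    """
    if len(rois) == 0:
        raise ValueError("at least one ROI is required")
    cache: dict[str, list[NucleusRecord]] = {}

    def cached(roi: RoiAnnotation) -> list[NucleusRecord]:
        if roi.id not in cache:
            cache[roi.id] = analyze_fn(roi)
        return cache[roi.id]

    acc = accrete_rois(rois, cached, policy, 20)

    reflex = False
    if monosomy_reflex and not policy.aneusomy_mode:
        candidates = [n for n in acc.all_nuclei if not n.edge_touching]
        low_cep = [n for n in candidates if n.cep17_count < 2]
        if candidates and len(low_cep) / len(candidates) >= MONOSOMY_REFLEX_FRACTION:
            reflex = True
            policy = MONOSOMY_POLICY
            acc = accrete_rois(rois, cached, policy, 20)

    n_required = 20
    borderline_pass = False
    if acc.insufficient:
        result = finalize(quantify(acc.reportable, 20)) if acc.reportable else QuantResult(
            0, float("nan"), float("nan"), float("nan"), insufficient=True
        )
    else:
        result = finalize(quantify(acc.reportable, 20))
        if result.borderline:
            borderline_pass = True
            n_required = 40
            acc = accrete_rois(rois, cached, policy, 40)
            result = finalize(quantify(acc.reportable, 40))

    analyzable = not result.insufficient and result.ish_group is not None
    detected = len(acc.all_nuclei)
    size_mb = acc.total_size_mb
    return CaseReport(
        case_id=case_id,
        result=result,
        analyzable=analyzable,
        policy=policy,
        n_required=n_required,
        used_roi_ids=[r.id for r in acc.used_rois],
        per_roi_counts=acc.per_roi_counts,
        detected_nuclei=detected,
        size_mb_used=size_mb,
        nuclei_per_mb=(detected / size_mb) if size_mb > 0 else 0.0,
        borderline_pass=borderline_pass,
        monosomy_reflex=reflex,
        provenance=provenance or {},
    )
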