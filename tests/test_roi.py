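"""ROI annotations, accretion stopping rule, and the case workflow."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from her2ish.roi import (
    AccretionResult,
    RoiAnnotation,
    accrete_rois,
    check_non_overlapping,
    nuclei_per_mb,
    rectangle_roi,
    rois_from_geojson,
    rois_to_geojson,
    run_case,
)
from her2ish.scoring import DEFAULT_POLICY
from her2ish.segment import NucleusRecord


def stub_nuclei(counts, roi_id="", edge=()):
    return [
        NucleusRecord(
            label=i + 1, centroid_xy=(float(i), 0.0), area_um2=50.0, solidity=1.0,
            circularity=1.0, mean_concentration=0.7, her2_count=h, cep17_count=c,
            edge_touching=(i in edge), roi_id=roi_id,
        )
        for i, (h, c) in enumerate(counts)
    ]


def stub_analyzer(per_roi: dict):
    calls = []

    def analyze(roi):
        calls.append(roi.id)
        return stub_nuclei(per_roi[roi.id], roi_id=roi.id)

    analyze.calls = calls
    return analyze


def rois(n, side_um=100.0, res=0.2):
    return [rectangle_roi(f"r{i}", i * (side_um + 10), 0.0, side_um, side_um, res) for i in range(n)]


class TestRoiAnnotation:
    def test_pixel_bbox_and_size(self):
        roi = rectangle_roi("a", 0.0, 0.0, 100.0, 50.0, 0.2)
        assert roi.pixel_bbox == (0, 0, 500, 250)
        assert roi.size_mb == pytest.approx(500 * 250 * 3 / 1e6)

    def test_clone_to_other_resolution(self):
        roi = rectangle_roi("a", 0.0, 0.0, 100.0, 50.0, 0.2)
        clone = roi.with_resolution(0.1)
        assert clone.polygon.equals(roi.polygon)
        assert clone.pixel_bbox == (0, 0, 1000, 500)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            RoiAnnotation("bad", Polygon([(0, 0), (1, 0), (2, 0)]), 0.2)

    def test_geojson_round_trip(self, tmp_path):
        original = rois(3)
        path = tmp_path / "rois.geojson"
        rois_to_geojson(original, path)
        loaded = rois_from_geojson(path)
        assert [r.id for r in loaded] == [r.id for r in original]
        assert all(a.polygon.equals(b.polygon) for a, b in zip(loaded, original))

    def test_overlap_detection_names_pair(self):
        a = rectangle_roi("alpha", 0.0, 0.0, 100.0, 100.0, 0.2)
        b = rectangle_roi("beta", 50.0, 0.0, 100.0, 100.0, 0.2)
        with pytest.raises(ValueError, match="alpha.*beta"):
            check_non_overlapping([a, b])


class TestAccretion:
    def test_single_roi_sufficient(self):
        analyze = stub_analyzer({"r0": [(3, 3)] * 25, "r1": [(3, 3)] * 25})
        acc = accrete_rois(rois(2), analyze, DEFAULT_POLICY, 20)
        assert [r.id for r in acc.used_rois] == ["r0"]
        assert analyze.calls == ["r0"]  # stopping rule: r1 never analyzed
        assert len(acc.reportable) == 25 and not acc.insufficient

    def test_two_rois_pooled(self):
        analyze = stub_analyzer({"r0": [(3, 3)] * 12, "r1": [(3, 3)] * 10, "r2": [(3, 3)] * 9})
        acc = accrete_rois(rois(3), analyze, DEFAULT_POLICY, 20)
        assert [r.id for r in acc.used_rois] == ["r0", "r1"]
        assert len(acc.reportable) == 22

    def test_trailing_roi_never_changes_result(self):
        per = {"r0": [(3, 3)] * 25, "r1": [(9, 9)] * 30}
        one = accrete_rois(rois(1), stub_analyzer(per), DEFAULT_POLICY, 20)
        two = accrete_rois(rois(2), stub_analyzer(per), DEFAULT_POLICY, 20)
        assert [r.id for r in one.used_rois] == [r.id for r in two.used_rois]
        assert [n.label for n in one.reportable] == [n.label for n in two.reportable]

    def test_exhaustion_flags_insufficiency(self):
        analyze = stub_analyzer({"r0": [(3, 3)] * 6, "r1": [(3, 3)] * 5})
        acc = accrete_rois(rois(2), analyze, DEFAULT_POLICY, 20)
        assert acc.insufficient and len(acc.reportable) == 11

    def test_n_required_validated(self):
        with pytest.raises(ValueError):
            accrete_rois(rois(1), stub_analyzer({"r0": []}), DEFAULT_POLICY, 30)

    def test_nuclei_per_mb(self):
        two_mb = [rectangle_roi("a", 0, 0, 471.4, 471.4, 0.2)]  # ~2.0 MB
        assert nuclei_per_mb(40, two_mb) == pytest.approx(40 / two_mb[0].size_mb)
        assert nuclei_per_mb(0, two_mb) == 0.0
        with pytest.raises(ValueError):
            nuclei_per_mb(10, [])


class TestRunCase:
    def test_clear_case_single_pass(self):
        analyze = stub_analyzer({"r0": [(9, 2)] * 25, "r1": [(9, 2)] * 25})
        report = run_case(rois(2), analyze, case_id="clear")
        assert report.analyzable
        assert report.result.ish_group == 1
        assert report.result.n_reported == 20
        assert not report.borderline_pass
        assert report.used_roi_ids == ["r0"]

    def test_borderline_case_extends_to_forty(self):
        # means 3.9/2.0 -> ratio 1.95: group 5 inside the borderline band
        counts = [(4, 2)] * 18 + [(3, 2)] * 2
        analyze = stub_analyzer({f"r{i}": counts for i in range(3)})
        report = run_case(rois(3), analyze, case_id="borderline")
        assert report.borderline_pass
        assert report.n_required == 40
        assert report.result.n_reported == 40
        assert report.result.ish_group == 5

    def test_insufficient_case_is_na(self):
        analyze = stub_analyzer({"r0": [(1, 1)] * 30})
        report = run_case(rois(1), analyze, case_id="na")
        assert not report.analyzable
        assert report.result.ish_group is None and report.result.status is None

    def test_monosomy_reflex_recovers_low_cep17_case(self):
        # most nuclei carry a single CEP17 signal: the standard filter would
        # retain almost nothing and bias the ratio down
        counts = ([(3, 1)] * 30 + [(3, 2)] * 8)
        analyze = stub_analyzer({f"r{i}": counts for i in range(2)})
        report = run_case(rois(2), analyze, case_id="mono")
        assert report.monosomy_reflex
        assert report.policy.min_cep17 == 1
        assert report.analyzable

    def test_each_roi_analyzed_once(self):
        analyze = stub_analyzer({f"r{i}": [(4, 2)] * 15 for i in range(3)})
        report = run_case(rois(3), analyze, case_id="cache")
        assert sorted(set(analyze.calls)) == sorted(analyze.calls)

    def test_report_round_trips_to_json(self, tmp_path):
        analyze = stub_analyzer({"r0": [(9, 2)] * 25})
        report = run_case(rois(1), analyze, case_id="c1")
        path = tmp_path / "report.json"
        report.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["schema"].startswith("her2ish/case-report-")
        assert data["result"]["ish_group"] == 1

    def test_label_permutation_invariance(self):
        counts = [(int(h), int(c)) for h, c in zip(
            np.random.default_rng(1).poisson(5, 30), np.random.default_rng(2).poisson(2, 30) + 2
        )]
        base = stub_nuclei(counts, roi_id="r0")
        shuffled = [base[i] for i in np.random.default_rng(3).permutation(len(base))]
        r1 = run_case(rois(1), lambda roi: base, case_id="a")
        r2 = run_case(rois(1), lambda roi: shuffled, case_id="a")
        assert r1.result == r2.result
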