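"""ASCO/CAP scoring: golden clinical cases, partition property, filters."""

import math
from dataclasses import dataclass, field

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from her2ish.clinical import REFERENCE_CASES, SELF_CONSISTENT_CASE_IDS, cases_with_fish
from her2ish.scoring import (
    AMPLIFIED,
    ANEUSOMY_POLICY,
    DEFAULT_POLICY,
    MONOSOMY_POLICY,
    NON_AMPLIFIED,
    InclusionPolicy,
    QuantResult,
    classify_ish_group,
    filter_reportable,
    finalize,
    her2_status,
    is_borderline,
    quantify,
)


@dataclass
class FakeNucleus:
    her2_count: int
    cep17_count: int
    edge_touching: bool = False
    area_um2: float = 50.0
    label: int = 0
    roi_id: str = ""
    reportable: bool = False


def make_nuclei(counts, **kw):
    return [FakeNucleus(h, c, label=i, **kw) for i, (h, c) in enumerate(counts)]


class TestClassification:
    def test_golden_clinical_groups(self):
        """The bundled FISH quantities reproduce the recorded ISH groups."""
        for case in cases_with_fish():
            assert classify_ish_group(case.fish_ratio, case.her2_per_nucleus) == case.ish_group, case

    def test_golden_clinical_status(self):
        for case in cases_with_fish():
            expected = AMPLIFIED if case.amplified else NON_AMPLIFIED
            assert her2_status(case.fish_ratio, case.her2_per_nucleus) == expected, case

    def test_printed_ratio_equals_rounded_mean_quotient(self):
        """For the self-consistent cases the recorded ratio is the 2-decimal
        rounding of HER2/CEP17 mean signals per nucleus."""
        by_id = {c.case_id: c for c in REFERENCE_CASES}
        for cid in SELF_CONSISTENT_CASE_IDS:
            c = by_id[cid]
            assert round(c.her2_per_nucleus / c.cep17_per_nucleus, 2) == c.fish_ratio

    @pytest.mark.parametrize(
        "ratio,copies,group",
        [
            (2.0, 4.0, 1),   # both boundaries inclusive
            (2.0, 3.99, 2),
            (1.99, 6.0, 3),
            (1.99, 4.0, 4),
            (1.99, 5.99, 4),
            (1.99, 3.99, 5),
            (0.0, 0.0, 5),
        ],
    )
    def test_boundaries(self, ratio, copies, group):
        assert classify_ish_group(ratio, copies) == group

    def test_status_boundary(self):
        assert her2_status(1.99, 100.0) == NON_AMPLIFIED
        assert her2_status(2.0, 4.0) == AMPLIFIED

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_ish_group(float("nan"), 4.0)
        with pytest.raises(ValueError):
            her2_status(2.0, float("nan"))

    @settings(derandomize=True, max_examples=300)
    @given(
        ratio=st.floats(0, 12, allow_nan=False),
        copies=st.floats(0, 25, allow_nan=False),
    )
    def test_partition_and_status_consistency(self, ratio, copies):
        """Every (ratio, copies) point receives exactly one group; amplified
        status holds exactly for group 1."""
        group = classify_ish_group(ratio, copies)
        regions = [
            ratio >= 2.0 and copies >= 4.0,
            ratio >= 2.0 and copies < 4.0,
            ratio < 2.0 and copies >= 6.0,
            ratio < 2.0 and 4.0 <= copies < 6.0,
            ratio < 2.0 and copies < 4.0,
        ]
        assert sum(regions) == 1
        assert regions[group - 1]
        assert (her2_status(ratio, copies) == AMPLIFIED) == (group == 1)


class TestFilter:
    def test_default_policy_rule(self):
        nuclei = make_nuclei([(2, 2), (1, 2), (5, 0)])
        kept = filter_reportable(nuclei, DEFAULT_POLICY)
        assert [(n.her2_count, n.cep17_count) for n in kept] == [(2, 2)]
        assert kept[0].reportable

    def test_monosomy_and_aneusomy_minima(self):
        nuclei = make_nuclei([(2, 2), (1, 2), (5, 0), (2, 1)])
        assert len(filter_reportable(nuclei, MONOSOMY_POLICY)) == 2  # (2,2),(2,1)
        assert len(filter_reportable(nuclei, ANEUSOMY_POLICY)) == 3  # all but (5,0)

    def test_edge_touching_excluded(self):
        nuclei = make_nuclei([(3, 3)], edge_touching=True)
        assert filter_reportable(nuclei, DEFAULT_POLICY) == []

    @settings(derandomize=True, max_examples=50)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 8), st.booleans()),
            max_size=200,
        ),
        minima=st.tuples(st.integers(0, 3), st.integers(0, 3)),
    )
    def test_matches_bruteforce_oracle(self, counts, minima):
        nuclei = [FakeNucleus(h, c, edge_touching=e, label=i) for i, (h, c, e) in enumerate(counts)]
        policy = InclusionPolicy(*minima)
        expected = [
            n for n in nuclei
            if n.her2_count >= minima[0] and n.cep17_count >= minima[1] and not n.edge_touching
        ]
        assert filter_reportable(nuclei, policy) == expected


class TestQuantify:
    def test_twenty_identical_nuclei(self):
        res = quantify(make_nuclei([(4, 2)] * 20), 20)
        assert (res.n_reported, res.mean_her2_per_cell, res.mean_cep17_per_cell) == (20, 4.0, 2.0)
        assert res.ratio == pytest.approx(2.0)
        assert not res.insufficient

    def test_case9_like_means(self):
        """Sample means matching a strongly amplified case give the recorded
        ratio at 2-decimal rounding."""
        # 100 nuclei engineered to average 11.19 HER2 and 4.5 CEP17
        h = [11] * 81 + [12] * 19
        hsum = sum(h)
        h[0] += 1119 - hsum
        c = [4] * 50 + [5] * 50
        res = quantify([FakeNucleus(hh, cc, label=i) for i, (hh, cc) in enumerate(zip(h, c))], 100)
        assert round(res.ratio, 2) == 2.49
        assert res.mean_her2_per_cell == pytest.approx(11.19)

    def test_ratio_equals_sum_form(self):
        rng = np.random.default_rng(5)
        nuclei = make_nuclei([(int(a), int(b)) for a, b in zip(rng.poisson(4, 50), rng.poisson(2, 50) + 2)])
        res = quantify(nuclei, 50)
        hsum = sum(n.her2_count for n in nuclei)
        csum = sum(n.cep17_count for n in nuclei)
        assert res.ratio == pytest.approx(hsum / csum)

    def test_permutation_invariance_when_all_reported(self):
        rng = np.random.default_rng(7)
        nuclei = make_nuclei([(int(a), 2) for a in rng.poisson(5, 30)])
        res1 = quantify(nuclei, 30)
        perm = [nuclei[i] for i in rng.permutation(30)]
        res2 = quantify(perm, 30)
        assert res1 == res2

    def test_selection_is_area_ordered(self):
        small = [FakeNucleus(2, 2, area_um2=30.0, label=i) for i in range(20)]
        big = [FakeNucleus(8, 2, area_um2=90.0, label=100 + i) for i in range(20)]
        res = quantify(small + big, 20)
        assert res.mean_her2_per_cell == 8.0  # largest nuclei reported first

    def test_n_to_report_bounds(self):
        with pytest.raises(ValueError):
            quantify(make_nuclei([(2, 2)] * 25), 19)
        with pytest.raises(ValueError):
            quantify(make_nuclei([(2, 2)] * 25), 201)

    def test_insufficient_and_empty(self):
        res = quantify(make_nuclei([(2, 2)] * 5), 20)
        assert res.insufficient and res.n_reported == 5
        res0 = quantify([], 20)
        assert res0.insufficient and res0.n_reported == 0 and math.isnan(res0.ratio)
        assert finalize(res0).ish_group is None


class TestBorderline:
    def test_group_rules(self):
        assert is_borderline(finalize(quantify(make_nuclei([(5, 4)] * 20), 20)))  # group 4
        clear = finalize(quantify(make_nuclei([(19, 2)] * 20), 20))  # ratio 9.5, group 1
        assert not is_borderline(clear)

    def test_ratio_band(self):
        # means 3.8 HER2 / 2.0 CEP17: ratio 1.9, group 5, inside the band
        near = finalize(quantify(make_nuclei([(4, 2)] * 16 + [(3, 2)] * 4), 20))
        assert near.ish_group == 5 and is_borderline(near)

    def test_requires_group(self):
        with pytest.raises(ValueError):
            is_borderline(QuantResult(20, 4.0, 2.0, 2.0))
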