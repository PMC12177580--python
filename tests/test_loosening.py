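"""Loosening-rate pipeline: filtering, association, rating, classification."""

from __future__ import annotations

import numpy as np
import pytest

from loosenrate.geometry import Box, intersection_area
from loosenrate.loosening import (
    BunchAssessment,
    Detection,
    LooseningConfig,
    ObjectClass,
    assess_scene,
    assign_stems_to_bunches,
    classify_bunch,
    filter_by_confidence,
    loosening_rate,
)

from conftest import rand_box


def det(x1, y1, x2, y2, conf=1.0, label=ObjectClass.STEM):
    return Detection(Box(x1, y1, x2, y2), conf, label)


def brute_force_assignment(stems, bunches, rule):
    """Exhaustive all-pairs oracle for the stem-to-bunch count mapping."""
    counts = {i: 0 for i in range(len(bunches))}
    for s in stems:
        areas = [intersection_area(s.box, b.box) for b in bunches]
        hit = [i for i, a in enumerate(areas) if a > 0]
        if not hit:
            continue
        if rule == "all":
            for i in hit:
                counts[i] += 1
        else:
            best_area = max(areas[i] for i in hit)
            counts[min(i for i in hit if areas[i] == best_area)] += 1
    return counts


class TestFilterByConfidence:
    def test_zero_threshold_is_identity(self):
        dets = [det(0, 0, 1, 1, c) for c in (0.0, 0.4, 1.0)]
        assert filter_by_confidence(dets, 0.0) == dets

    def test_threshold_one_keeps_only_certain(self):
        dets = [det(0, 0, 1, 1, c) for c in (0.99, 1.0)]
        assert filter_by_confidence(dets, 1.0) == [dets[1]]

    def test_boundary_survives(self):
        dets = [det(0, 0, 1, 1, c) for c in (0.2, 0.3, 0.31)]
        kept = filter_by_confidence(dets, 0.30)
        assert [d.conf for d in kept] == [0.3, 0.31]

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_by_confidence([], 1.5)


class TestAssignment:
    def test_single_bunch_counts_overlapping_only(self):
        bunch = det(0, 0, 100, 100, label=ObjectClass.BUNCH)
        inside = [det(10 * i, 10, 10 * i + 20, 40) for i in range(3)]
        outside = [det(200, 200, 220, 220), det(300, 5, 320, 25)]
        assert assign_stems_to_bunches(inside + outside, [bunch]) == {0: 3}

    def test_no_bunches_empty_mapping(self):
        assert assign_stems_to_bunches([det(0, 0, 5, 5)], []) == {}

    def test_max_intersection_prefers_larger_overlap(self):
        # stem overlaps bunch A with area 4 and bunch B with area 1
        a = det(0, 0, 4, 4, label=ObjectClass.BUNCH)
        b = det(5, 0, 9, 4, label=ObjectClass.BUNCH)
        stem = det(2, 0, 6, 2)  # 2x2 = 4 in A, 1x... (5..6)x(0..2) = 2 in B
        assert intersection_area(stem.box, a.box) > intersection_area(stem.box, b.box)
        assert assign_stems_to_bunches([stem], [a, b]) == {0: 1, 1: 0}

    def test_tie_breaks_to_lowest_index(self):
        a = det(0, 0, 4, 4, label=ObjectClass.BUNCH)
        b = det(4, 0, 8, 4, label=ObjectClass.BUNCH)
        stem = det(3, 0, 5, 2)  # area 2 in each
        assert assign_stems_to_bunches([stem], [a, b]) == {0: 1, 1: 0}
        assert assign_stems_to_bunches([stem], [b, a]) == {0: 1, 1: 0}

    def test_rule_all_counts_everywhere(self):
        a = det(0, 0, 4, 4, label=ObjectClass.BUNCH)
        b = det(3, 0, 8, 4, label=ObjectClass.BUNCH)
        stem = det(2, 0, 5, 2)
        assert assign_stems_to_bunches([stem], [a, b], rule="all") == {0: 1, 1: 1}

    def test_edge_contact_is_not_overlap(self):
        bunch = det(0, 0, 10, 10, label=ObjectClass.BUNCH)
        stem = det(10, 0, 20, 10)
        assert assign_stems_to_bunches([stem], [bunch]) == {0: 0}

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            assign_stems_to_bunches([], [], rule="nearest")

    @pytest.mark.parametrize("rule", ["max_intersection", "all"])
    def test_matches_brute_force_on_random_scenes(self, rng, rule):
        for _ in range(100):
            n_stems = int(rng.integers(0, 40))
            n_bunches = int(rng.integers(0, 6))
            stems = [
                Detection(rand_box(rng, frame=500), 1.0, ObjectClass.STEM)
                for _ in range(n_stems)
            ]
            bunches = [
                Detection(rand_box(rng, frame=500, max_size=400), 1.0, ObjectClass.BUNCH)
                for _ in range(n_bunches)
            ]
            assert assign_stems_to_bunches(stems, bunches, rule) == \
                brute_force_assignment(stems, bunches, rule)

    def test_max_intersection_counts_each_stem_at_most_once(self, rng):
        for _ in range(50):
            stems = [Detection(rand_box(rng, frame=300), 1.0, ObjectClass.STEM)
                     for _ in range(int(rng.integers(1, 30)))]
            bunches = [Detection(rand_box(rng, frame=300, max_size=250), 1.0,
                                 ObjectClass.BUNCH)
                       for _ in range(int(rng.integers(1, 5)))]
            counts = assign_stems_to_bunches(stems, bunches)
            assert sum(counts.values()) <= len(stems)


class TestRateAndVerdict:
    @pytest.mark.parametrize("x, lam, expected", [(4, 8, 200.0), (8, 8, 100.0),
                                                  (16, 8, 50.0), (3, 6, 200.0)])
    def test_rate_values(self, x, lam, expected):
        assert loosening_rate(x, lam) == pytest.approx(expected)

    def test_rate_undefined_for_empty_bunch(self):
        with pytest.raises(ValueError, match="undefined"):
            loosening_rate(0, 8)

    def test_qualified_strictly_below_lambda(self):
        assert classify_bunch(7, 8) is True
        assert classify_bunch(8, 8) is False
        assert classify_bunch(9, 8) is False

    def test_empty_bunch_qualified_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert classify_bunch(0, 8) is True
        assert any("no overlapping stem" in r.message for r in caplog.records)

    def test_verdict_consistent_with_rate(self):
        # qualified <=> R > 100 % (x >= 1)
        for x in range(1, 20):
            assert classify_bunch(x, 8) == (loosening_rate(x, 8) > 100.0)


class TestAssessScene:
    def test_empty_input(self):
        assert assess_scene([], LooseningConfig()) == []

    def test_single_overcrowded_bunch(self):
        bunch = det(0, 0, 1000, 1000, conf=0.9, label=ObjectClass.BUNCH)
        stems = [det(100 * i, 100, 100 * i + 80, 180, conf=0.9) for i in range(9)]
        out = assess_scene([bunch] + stems, LooseningConfig(lam=8, conf_threshold=0.30))
        assert len(out) == 1
        a = out[0]
        assert (a.x, a.qualified) == (9, False)
        assert a.rate == pytest.approx(800 / 9)

    def test_high_threshold_filters_everything(self):
        bunch = det(0, 0, 1000, 1000, conf=0.9, label=ObjectClass.BUNCH)
        stems = [det(100 * i, 100, 100 * i + 80, 180, conf=0.9) for i in range(9)]
        assert assess_scene([bunch] + stems,
                            LooseningConfig(lam=8, conf_threshold=0.95)) == []

    def test_empty_bunch_flagged_qualified(self):
        bunch = det(0, 0, 50, 50, conf=0.8, label=ObjectClass.BUNCH)
        out = assess_scene([bunch], LooseningConfig())
        assert out[0].x == 0 and out[0].rate is None and out[0].qualified

    def test_adding_overlapping_stem_never_raises_rate(self, rng):
        """Monotonicity: more members -> lower (or equal) rate, and an
        unqualified bunch can never become qualified."""
        bunch = det(0, 0, 400, 400, conf=1.0, label=ObjectClass.BUNCH)
        dets = [bunch]
        prev_rate = None
        prev_qualified = True
        cfg = LooseningConfig(lam=8, conf_threshold=0.0)
        for i in range(15):
            x1 = float(rng.uniform(0, 350))
            y1 = float(rng.uniform(0, 350))
            dets.append(det(x1, y1, x1 + 40, y1 + 40, conf=1.0))
            a = assess_scene(dets, cfg)[0]
            if prev_rate is not None:
                assert a.rate <= prev_rate
            if not prev_qualified:
                assert not a.qualified
            prev_rate, prev_qualified = a.rate, a.qualified

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LooseningConfig(lam=0)
        with pytest.raises(ValueError):
            LooseningConfig(conf_threshold=1.2)
        with pytest.raises(ValueError):
            LooseningConfig(multi_overlap_rule="bogus")
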