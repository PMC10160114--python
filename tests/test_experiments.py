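"""Split construction, crop-overlap geometry, the experiment runner."""

import dataclasses
import math

import numpy as np
import pytest

from wsilink import (
    ExperimentConfig,
    ImageThumb,
    Manifest,
    SetSplit,
    SlideRecord,
    BackgroundItem,
    build_distance_threshold_sets,
    crop_with_shift,
    overlap_fraction,
    run_experiment,
    split_pairs,
    sweep_patients,
    sweep_probes,
)


def _manifest(spec):
    """spec: {patient: [positions]} -> Manifest with synthetic slide ids."""
    records = [
        SlideRecord(patient_id=h, slide_id=f"{h}-s{i}", section_position_mm=pos)
        for h, positions in spec.items()
        for i, pos in enumerate(positions)
    ]
    return Manifest(records=records)


class TestSplitPairs:
    def test_pair_cohort_sizes(self):
        m = _manifest({f"h{i}": [0.0, 4.0] for i in range(28)})
        split = split_pairs(m, seed=1)
        assert len(split.background) == 28 and len(split.probe_ids) == 28
        assert all(len(split.truth[h]) == 1 for h in m.patients)

    def test_deterministic_per_seed(self):
        m = _manifest({f"h{i}": [0.0, 3.0] for i in range(10)})
        assert split_pairs(m, seed=5) == split_pairs(m, seed=5)
        assert any(
            split_pairs(m, seed=5).background != split_pairs(m, seed=s).background
            for s in range(6, 12)
        )

    def test_non_pair_patient_rejected(self):
        m = _manifest({"h0": [0.0, 3.0, 6.0], "h1": [0.0, 3.0]})
        with pytest.raises(ValueError, match="exactly 2"):
            split_pairs(m, seed=0)

    def test_background_and_probes_disjoint(self):
        m = _manifest({f"h{i}": [0.0, 3.0] for i in range(10)})
        split = split_pairs(m, seed=2)
        assert not set(i.item_id for i in split.background) & set(split.probe_ids)


class TestDistanceThreshold:
    def test_probes_follow_strict_distance_rule(self):
        # oracle: recompute the probe set from the chosen pivot for many seeds
        m = _manifest({"h0": [0.0, 3.0, 6.0], "h1": [0.0, 4.0, 8.0, 12.0]})
        positions = {r.slide_id: r.section_position_mm for r in m.records}
        for seed in range(30):
            for l in (0.0, 3.0, 4.0, 10.0):
                split = build_distance_threshold_sets(m, l, seed=seed)
                for item in split.background:
                    pivot_pos = positions[item.item_id]
                    expected = {
                        r.slide_id
                        for r in m.records
                        if r.patient_id == item.patient_id
                        and r.slide_id != item.item_id
                        and abs(r.section_position_mm - pivot_pos) > l
                    }
                    assert split.truth[item.patient_id] == expected

    def test_block_span_example(self):
        # positions 0/3/6 mm with l=4: from pivot 3 nothing is farther than 4;
        # from pivot 0 only the 6 mm slide (3 mm + 3 mm) is included
        m = _manifest({"h0": [0.0, 3.0, 6.0]})
        seen = set()
        for seed in range(40):
            split = build_distance_threshold_sets(m, 4.0, seed=seed)
            pivot = split.background[0].item_id
            seen.add(pivot)
            expected = {"h0-s0": {"h0-s2"}, "h0-s1": set(), "h0-s2": {"h0-s0"}}[pivot]
            assert split.truth["h0"] == expected
        assert seen == {"h0-s0", "h0-s1", "h0-s2"}  # every pivot exercised

    def test_l_zero_takes_all_non_pivot_slides(self):
        m = _manifest({"h0": [0.0, 3.0, 6.0]})
        split = build_distance_threshold_sets(m, 0.0, seed=3)
        assert len(split.truth["h0"]) == 2

    def test_l_beyond_block_span_empties_probes(self):
        m = _manifest({"h0": [0.0, 3.0, 6.0], "h1": [0.0, 5.0]})
        split = build_distance_threshold_sets(m, 50.0, seed=3)
        assert split.probe_ids == ()
        assert all(split.truth[h] == frozenset() for h in m.patients)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_distance_threshold_sets(_manifest({"h0": [0.0]}), -1.0, seed=0)


class TestSweeps:
    def test_patient_sweep_subset_and_probe_rule(self):
        m = _manifest({f"h{i}": [0.0, 3.0, 7.0] for i in range(10)})
        split = sweep_patients(m, 4, seed=9)
        assert len(split.background) == 4
        assert all(len(split.truth[i.patient_id]) == 2 for i in split.background)

    def test_single_slide_patient_contributes_empty_probe_set(self):
        m = _manifest({"h0": [0.0], "h1": [0.0, 3.0]})
        split = sweep_patients(m, 2, seed=1)
        assert split.truth["h0"] == frozenset()

    def test_out_of_range_n_rejected(self):
        m = _manifest({"h0": [0.0]})
        for n in (0, 2):
            with pytest.raises(ValueError):
                sweep_patients(m, n, seed=0)

    def test_probe_sweep_eligibility(self):
        m = _manifest({"h0": [float(i) for i in range(7)], "h1": [0.0, 3.0]})
        split = sweep_probes(m, 6, seed=4)  # needs >= 7 slides
        assert [i.patient_id for i in split.background] == ["h0"]
        assert len(split.truth["h0"]) == 6

    def test_probe_sweep_exact_probe_count_and_determinism(self):
        m = _manifest({f"h{i}": [float(j) * 3 for j in range(5)] for i in range(6)})
        s1 = sweep_probes(m, 3, seed=8)
        s2 = sweep_probes(m, 3, seed=8)
        assert s1 == s2
        assert all(len(s1.truth[h]) == 3 for h in m.patients)

    def test_no_eligible_patient_is_an_error(self):
        m = _manifest({"h0": [0.0, 3.0]})
        with pytest.raises(ValueError, match="no patient"):
            sweep_probes(m, 5, seed=0)


class TestOverlapGeometry:
    def test_zero_shift_full_overlap(self):
        assert overlap_fraction(0.0, 123.0, 224) == 1.0

    def test_printed_axis_and_diagonal_values(self):
        # 50 px shift: 78% axis-aligned, 71% diagonal; 75 px: 67% and 58%
        assert overlap_fraction(50, 0, 224) == pytest.approx(1 - 50 / 224)
        assert round(100 * overlap_fraction(50, 0, 224)) == 78
        assert round(100 * overlap_fraction(50, 45, 224)) == 71
        assert round(100 * overlap_fraction(75, 0, 224)) == 67
        assert round(100 * overlap_fraction(75, 45, 224)) == 58

    def test_extremes_at_axis_and_diagonal(self):
        thetas = np.linspace(0, 360, 1441)
        vals = [overlap_fraction(60, t, 224) for t in thetas]
        assert max(vals) == pytest.approx(overlap_fraction(60, 0, 224))
        assert min(vals) == pytest.approx(overlap_fraction(60, 45, 224))

    def test_quarter_turn_symmetry(self):
        for t in (0.0, 17.0, 33.0, 61.0):
            assert overlap_fraction(40, t, 224) == pytest.approx(
                overlap_fraction(40, t + 90, 224)
            )

    def test_disjoint_windows_give_zero_not_error(self):
        assert overlap_fraction(300, 0, 224) == 0.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction(-1, 0, 224)
        with pytest.raises(ValueError):
            overlap_fraction(10, 0, 0)


class TestCropWithShift:
    def _pair(self, side=400):
        rng = np.random.default_rng(0)
        px = rng.uniform(0.2, 0.9, size=(side, side, 3))
        return ImageThumb(px, "a"), ImageThumb(px.copy(), "b")

    def test_zero_shift_identical_windows(self):
        a, b = self._pair()
        ca, cb, overlap = crop_with_shift(a, b, 224, 0.0, seed=1)
        assert overlap == 1.0
        np.testing.assert_array_equal(ca.pixels, cb.pixels)
        assert ca.provenance == "cropped"

    def test_overlap_matches_analytic_band(self):
        a, b = self._pair()
        lo = overlap_fraction(50, 45, 224)
        hi = overlap_fraction(50, 0, 224)
        for seed in range(20):
            _, _, overlap = crop_with_shift(a, b, 224, 50.0, seed=seed)
            assert lo - 1e-9 <= overlap <= hi + 1e-9

    def test_impossible_geometry_is_an_error(self):
        a, b = self._pair(side=240)
        with pytest.raises(ValueError, match="outside"):
            crop_with_shift(a, b, 224, 100.0, seed=0)


class TestSetSplitInvariants:
    def test_probe_in_background_rejected(self):
        with pytest.raises(ValueError, match="both background and probes"):
            SetSplit(
                (BackgroundItem("h0", "s0"),),
                {"h0": frozenset({"s0"})},
                ("s0",),
            )

    def test_truth_must_partition_probes(self):
        with pytest.raises(ValueError, match="partition"):
            SetSplit(
                (BackgroundItem("h0", "s0"),),
                {"h0": frozenset()},
                ("s1",),
            )


class TestRunExperiment:
    def test_repeats_and_reproducibility(self, small_cohort):
        manifest, images = small_cohort
        cfg = ExperimentConfig(design="sweep_patients", n_patients=5, repeats=6, seed=30)
        r1 = run_experiment(cfg, manifest, images, feature_cache={})
        r2 = run_experiment(cfg, manifest, images, feature_cache={})
        assert len(r1) == 6
        assert r1 == r2
        r3 = run_experiment(dataclasses.replace(cfg, seed=31), manifest, images)
        assert r1 != r3

    def test_incompatible_manifest_fails_before_running(self, small_cohort):
        manifest, images = small_cohort  # 3 slides/patient: not a pair cohort
        cfg = ExperimentConfig(design="E2a", repeats=3, seed=0)
        with pytest.raises(ValueError, match="pairs"):
            run_experiment(cfg, manifest, images)

    def test_design_parameter_consistency_enforced(self):
        with pytest.raises(ValueError, match="distance_threshold_mm"):
            ExperimentConfig(design="E2b")
        with pytest.raises(ValueError, match="n_patients"):
            ExperimentConfig(design="sweep_patients")
        with pytest.raises(ValueError, match="not supported"):
            ExperimentConfig(design="cE2b", distance_threshold_mm=3.0, shift_px=50.0)
        with pytest.raises(ValueError, match="unknown design"):
            ExperimentConfig(design="E9")

    def test_distance_threshold_runs_on_block_cohort(self, small_cohort):
        manifest, images = small_cohort
        cfg = ExperimentConfig(design="E2b", distance_threshold_mm=3.0, repeats=3, seed=12)
        results = run_experiment(cfg, manifest, images, feature_cache={})
        assert len(results) == 3
        assert all(0.0 <= r.rs <= 1.0 for r in results)
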