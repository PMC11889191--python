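"""Tests of pair counting, the normalized mixing score, aggregated
entropy, pattern classification and multi-core stitching."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_counts
from tmespat.config import SimConfig
from tmespat.spatial import (
    DEFAULT_RADII,
    InteractionCounts,
    aggregated_entropy,
    classify_pattern,
    count_interactions,
    entropy_gradient,
    nms,
    nms_curve,
    patient_spatial_analysis,
    stitch_cores,
    stitch_patient_cells,
)
from tmespat.synthetic import generate_cores

WORKED_REF = [(0.0, 0.0), (10.0, 0.0)]
WORKED_TGT = [(0.0, 5.0)]


class TestCountInteractions:
    def test_worked_point_set(self):
        c = count_interactions(WORKED_REF, WORKED_TGT, 10.0)
        assert (c.i_rt, c.i_rr, c.n_r, c.n_t) == (1, 1, 2, 1)

    def test_radius_below_all_distances(self):
        c = count_interactions(WORKED_REF, WORKED_TGT, 2.0)
        assert c.i_rt == 0 and c.i_rr == 0

    def test_duplicate_points_count_as_distinct_cells(self):
        c = count_interactions([(1.0, 1.0), (1.0, 1.0)], [(1.0, 1.0)], 0.5)
        assert c.i_rr == 1 and c.i_rt == 2

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            count_interactions(WORKED_REF, WORKED_TGT, -1.0)

    def test_matches_brute_force_on_random_sets(self, rng):
        """KD-tree counting equals the O(n^2) oracle exactly."""
        for _ in range(50):
            n_r, n_t = rng.integers(2, 120, 2)
            ref = rng.uniform(0, 500, (n_r, 2))
            tgt = rng.uniform(0, 500, (n_t, 2))
            r = float(rng.uniform(5, 250))
            c = count_interactions(ref, tgt, r)
            i_rt, i_rr = brute_force_counts(ref, tgt, r)
            assert (c.i_rt, c.i_rr) == (i_rt, i_rr)

    def test_counts_monotone_in_radius(self, rng):
        for _ in range(20):
            ref = rng.uniform(0, 600, (60, 2))
            tgt = rng.uniform(0, 600, (40, 2))
            prev_rt, prev_rr = -1, -1
            for r in DEFAULT_RADII:
                c = count_interactions(ref, tgt, r)
                assert c.i_rt >= prev_rt and c.i_rr >= prev_rr
                prev_rt, prev_rr = c.i_rt, c.i_rr


class TestNms:
    def test_worked_example_value(self):
        assert nms(count_interactions(WORKED_REF, WORKED_TGT, 10.0)) == 0.5

    def test_zero_cross_interactions(self):
        assert nms(InteractionCounts(i_rt=0, i_rr=3, n_r=4, n_t=5)) == 0.0

    def test_no_reference_pairs_is_missing(self):
        assert math.isnan(nms(InteractionCounts(i_rt=2, i_rr=0, n_r=4, n_t=5)))

    def test_too_few_reference_cells_rejected(self):
        with pytest.raises(ValueError):
            nms(InteractionCounts(i_rt=0, i_rr=0, n_r=1, n_t=5))

    def test_rigid_motion_invariance(self, rng):
        ref = rng.uniform(0, 300, (50, 2))
        tgt = rng.uniform(0, 300, (30, 2))
        base = nms(count_interactions(ref, tgt, 80.0))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([123.4, -55.0])
        moved = nms(count_interactions(ref @ rot.T + shift, tgt @ rot.T + shift, 80.0))
        assert moved == base

    def test_csr_null_is_near_one(self, rng):
        """Both classes from one homogeneous Poisson process: the score
        has no mixing signal and averages ~1 (reduced-size null here; the
        full 500-simulation check lives in the acceptance suite)."""
        side = 250.0
        vals = [
            nms(
                count_interactions(
                    rng.uniform(0, side, (100, 2)), rng.uniform(0, side, (100, 2)), 25.0
                )
            )
            for _ in range(100)
        ]
        assert 0.93 < np.nanmean(vals) < 1.07

    def test_singleton_ladder_curve(self):
        curve = nms_curve(WORKED_REF, WORKED_TGT, [10.0])
        assert len(curve) == 1 and curve["value"].iloc[0] == 0.5


class TestAggregatedEntropy:
    def test_no_targets_within_radius_gives_zero(self):
        assert aggregated_entropy([(0, 0), (5, 0)], [(500, 500)], 10.0) == 0.0

    def test_hand_computed_balanced_example(self):
        h = aggregated_entropy([(0, 0), (1, 0)], [(0, 1), (1, 1)], 2.0)
        assert h == 1.0

    def test_role_swap_symmetry(self, rng):
        """Swapping the pooled counts leaves the binary entropy unchanged;
        with symmetric point sets the roles can swap exactly."""
        pts_a = [(0.0, 0.0), (1.0, 0.0)]
        pts_b = [(0.0, 1.0), (1.0, 1.0)]
        assert aggregated_entropy(pts_a, pts_b, 2.0) == aggregated_entropy(
            pts_b, pts_a, 2.0
        )

    def test_no_reference_cells_rejected(self):
        with pytest.raises(ValueError):
            aggregated_entropy([], [(0, 0)], 10.0)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            ref = rng.uniform(0, 200, (rng.integers(1, 40), 2))
            tgt = rng.uniform(0, 200, (rng.integers(0, 40), 2))
            h = aggregated_entropy(ref, tgt, float(rng.uniform(10, 300)))
            assert 0.0 <= h <= 1.0


class TestEntropyGradient:
    def test_negative_slope_is_attraction(self):
        assert classify_pattern((0.7 - 0.9) / 50.0) == "attraction"

    def test_positive_slope_is_repulsion(self):
        assert classify_pattern((0.5 - 0.2) / 50.0) == "repulsion"

    def test_constant_curve_is_flat(self):
        assert classify_pattern(0.0) == "flat"
        assert classify_pattern(float("nan")) == "undefined"

    def test_slope_uses_first_two_radii(self, rng):
        ref = rng.uniform(0, 400, (60, 2))
        tgt = rng.uniform(0, 400, (60, 2))
        curve, slope, _ = entropy_gradient(ref, tgt, DEFAULT_RADII)
        h = curve["value"].to_numpy()
        assert slope == pytest.approx((h[1] - h[0]) / 50.0)

    def test_short_ladder_rejected(self):
        with pytest.raises(ValueError):
            entropy_gradient([(0, 0)], [(1, 1)], [50.0])


class TestStitching:
    def test_boundary_gap_exceeds_max_radius(self):
        offsets = stitch_cores({"a": (600.0, 600.0), "b": (600.0, 600.0)}, 600.0)
        (ax, ay), (bx, by) = offsets["a"], offsets["b"]
        gap = max(abs(ax - bx), abs(ay - by)) - 600.0
        assert gap > 600.0

    def test_single_core_identity(self):
        assert stitch_cores({"only": (500.0, 400.0)}, 600.0)["only"] == (0.0, 0.0)

    def test_stitched_counts_equal_per_core_sums(self, rng):
        """Interaction counts on the stitched frame decompose into the sum
        of per-core counts for random layouts."""
        for _ in range(30):
            n_cores = int(rng.integers(1, 4))
            rows = []
            for c in range(n_cores):
                n = int(rng.integers(5, 40))
                pts = rng.uniform(0, 600, (n, 2))
                for x, y in pts:
                    rows.append(
                        {
                            "core_id": f"C{c}",
                            "patient_id": "P0",
                            "x_um": x,
                            "y_um": y,
                            "cell_class": str(rng.choice(["ref", "tgt"])),
                        }
                    )
            cells = pd.DataFrame(rows)
            radius = float(rng.uniform(50, 600))
            stitched = stitch_patient_cells(cells, 600.0)
            ref_s = stitched[stitched.cell_class == "ref"][["x_um", "y_um"]].to_numpy()
            tgt_s = stitched[stitched.cell_class == "tgt"][["x_um", "y_um"]].to_numpy()
            c_st = count_interactions(ref_s, tgt_s, radius)
            i_rt = i_rr = 0
            for c in cells.core_id.unique():
                sub = cells[cells.core_id == c]
                a, b = brute_force_counts(
                    sub[sub.cell_class == "ref"][["x_um", "y_um"]].to_numpy(),
                    sub[sub.cell_class == "tgt"][["x_um", "y_um"]].to_numpy(),
                    radius,
                )
                i_rt += a
                i_rr += b
            assert (c_st.i_rt, c_st.i_rr) == (i_rt, i_rr)


class TestRegimeContrast:
    def test_short_range_nms_separates_attraction_from_repulsion(self):
        """At close-interaction radii (<= 250 um) attraction cores score
        above repulsion cores on average; at radii comparable to the core
        size the score saturates and loses mixing information."""
        radii = [r for r in DEFAULT_RADII if r <= 250.0]
        mean_curves = {}
        for regime in ("attraction", "repulsion"):
            curves = []
            for seed in range(20):
                cfg = SimConfig(
                    n_patients=1,
                    cores_per_patient=1,
                    mixing_regime=regime,
                    mixing_strength=30.0,
                    seed=seed,
                )
                cells, _, _ = generate_cores(cfg)
                cells = cells.rename(columns={"true_class": "cell_class"})
                out, _ = patient_spatial_analysis(
                    cells, reference_classes=("immune",), radii=radii
                )
                curves.append(
                    out[out.metric == "nms"].set_index("radius")["value"].to_numpy()
                )
            mean_curves[regime] = np.nanmean(np.array(curves), axis=0)
        assert (mean_curves["attraction"] > mean_curves["repulsion"]).all()

    def test_pipeline_patterns_match_regimes(self):
        """Entropy-gradient classification recovers the generating regime
        on a handful of cores (full 100+100 check in the acceptance suite)."""
        dens = {c: 500.0 for c in ("t_helper", "cytotoxic_t", "t_regulatory", "macrophage")}
        dens["tumor"] = 500.0
        for regime, expected in (("attraction", "attraction"), ("repulsion", "repulsion")):
            hits = 0
            for seed in range(5):
                cfg = SimConfig(
                    n_patients=1,
                    cores_per_patient=1,
                    cell_density_per_class=dens,
                    mixing_regime=regime,
                    mixing_strength=30.0,
                    seed=seed,
                )
                cells, _, _ = generate_cores(cfg)
                cells = cells.rename(columns={"true_class": "cell_class"})
                _, patterns = patient_spatial_analysis(
                    cells, reference_classes=("immune",)
                )
                hits += patterns["pattern"].iloc[0] == expected
            assert hits >= 4


class TestPatientAnalysis:
    def test_undefined_for_reference_poor_patients(self):
        cells = pd.DataFrame(
            {
                "patient_id": ["P0"] * 3,
                "core_id": ["C0"] * 3,
                "x_um": [1.0, 2.0, 3.0],
                "y_um": [1.0, 2.0, 3.0],
                "cell_class": ["tumor", "tumor", "cytotoxic_t"],
            }
        )
        curves, patterns = patient_spatial_analysis(
            cells, reference_classes=("cytotoxic_t",)
        )
        assert (patterns["pattern"] == "undefined").all()
        assert curves["value"].isna().all()
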