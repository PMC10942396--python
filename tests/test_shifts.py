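"""pRF center-shift summaries, shuffled control, directional vector bins."""

import numpy as np
import pandas as pd
import pytest

from anticiprf import design, glm, prf, shifts, synth
from anticiprf.shifts import (
    binned_shift_vectors,
    distance_change_to_target,
    shuffle_schedule_cues,
    shuffled_control,
)
from anticiprf.tuning import rotate_points


def _prf_table(per_condition_centers, map_label="V3", r2=0.9):
    """Tidy per-vertex x condition table from {cond: (n, 2) centers}."""
    rows = []
    n = len(next(iter(per_condition_centers.values())))
    for cond, centers in per_condition_centers.items():
        for v in range(n):
            x, y = centers[v]
            rows.append({
                "vertex": v, "map": map_label, "condition": cond,
                "x": x, "y": y, "sigma": 1.0, "gain": 1.0, "r2": r2,
                "eccentricity": np.hypot(x, y),
            })
    return pd.DataFrame(rows)


class TestDistanceChange:
    def test_no_shift_gives_zero(self):
        centers = {c: [(3.0, 1.0)] for c in list(design.FOCAL_CONDITIONS) + ["distributed"]}
        summary = distance_change_to_target(_prf_table(centers))
        assert summary.by_map.loc[0, "mean_change"] == pytest.approx(0.0)

    def test_arithmetic_example(self):
        # distributed (4,0), attend-right (4.5,0), target (6,0):
        # change = 1.5 - 2.0 = -0.5 for the right condition, 0 for the rest
        centers = {c: [(4.0, 0.0)] for c in list(design.FOCAL_CONDITIONS) + ["distributed"]}
        centers["right"] = [(4.5, 0.0)]
        summary = distance_change_to_target(_prf_table(centers))
        assert summary.per_vertex.loc[0, "change"] == pytest.approx(-0.5 / 4)

    def test_filters_require_all_five_models(self):
        centers = {c: [(3.0, 0.0)] for c in list(design.FOCAL_CONDITIONS) + ["distributed"]}
        table = _prf_table(centers)
        table.loc[table["condition"] == "up", "r2"] = 0.1  # one failing model
        summary = distance_change_to_target(table)
        assert summary.empty

    def test_invariant_under_joint_rotation(self):
        rng = np.random.default_rng(7)
        n = 20
        base = np.column_stack([rng.uniform(-4, 4, n), rng.uniform(-4, 4, n)])
        jitter = {c: base + rng.normal(0, 0.1, base.shape) for c in design.FOCAL_CONDITIONS}
        jitter["distributed"] = base
        phi = 53.0
        rotated = {
            c: np.column_stack(rotate_points(v[:, 0], v[:, 1], phi))
            for c, v in jitter.items()
        }
        targets0 = {c: shifts.target_center(c) for c in design.FOCAL_CONDITIONS}
        targets1 = {
            c: rotate_points(np.array([t[0]]), np.array([t[1]]), phi)
            for c, t in targets0.items()
        }
        targets1 = {c: (float(t[0][0]), float(t[1][0])) for c, t in targets1.items()}
        s0 = distance_change_to_target(_prf_table(jitter), targets=targets0)
        s1 = distance_change_to_target(_prf_table(rotated), targets=targets1)
        assert s0.by_map.loc[0, "mean_change"] == pytest.approx(
            s1.by_map.loc[0, "mean_change"], abs=1e-9
        )

    def test_attention_field_truth_recovered_with_ordering(self, apertures64):
        # noiseless loop: larger pRFs (steeper size-ecc slope) shift more
        rng = np.random.default_rng(11)
        vertices = []
        for label, slope in (("V3", 0.2), ("hV4", 0.5)):
            for _ in range(8):
                r = rng.uniform(1.5, 5.0)
                th = rng.uniform(0, 2 * np.pi)
                vertices.append(synth.GroundTruthVertex(
                    label, r * np.cos(th), r * np.sin(th), 0.5 + slope * r
                ))
        synth.apply_attention(
            vertices, synth.AttentionFieldSpec(mode="position_only", sigma_attn=4.0)
        )
        betas = synth.simulate_beta_truth(vertices, apertures64)
        table = prf.fit_population_by_condition(
            betas, apertures64, map_labels=[v.map_label for v in vertices]
        )
        summary = distance_change_to_target(table[table["condition"] != "average"])
        by_map = summary.by_map.set_index("map")["mean_change"]
        assert (by_map < 0).all()
        assert by_map["hV4"] < by_map["V3"]  # larger configured shift


class TestShuffledControl:
    def test_identity_permutation_reproduces_pipeline(self, apertures64, hrf):
        rng = np.random.default_rng(3)
        vertices = [
            synth.GroundTruthVertex(
                "V3", *rng.uniform(-3.5, 3.5, 2), sigma0=rng.uniform(0.8, 2.0)
            )
            for _ in range(6)
        ]
        synth.apply_attention(
            vertices, synth.AttentionFieldSpec(mode="position_only", sigma_attn=3.0)
        )
        truth = synth.simulate_beta_truth(vertices, apertures64)
        sched = design.build_balanced_schedule(repeats=1, seed=2)
        series = synth.simulate_bold(truth, sched, hrf=hrf, seed=1)
        kwargs = dict(apertures=apertures64, hrf=hrf, map_labels=["V3"] * 6)
        direct = shuffled_control(series, sched, seed=None, **kwargs)
        again = shuffled_control(series, sched, seed=None, **kwargs)
        assert np.allclose(
            direct.by_map["mean_change"], again.by_map["mean_change"]
        )
        # the unshuffled pipeline recovers a negative (toward-target) change
        assert direct.by_map.loc[0, "mean_change"] < 0

    def test_shuffle_preserves_trial_timing(self):
        sched = design.build_trial_schedule(100, seed=5)
        shuffled = shuffle_schedule_cues(sched, seed=6)
        assert [t.onset_tr for t in shuffled] == [t.onset_tr for t in sched]
        assert sorted(t.cue for t in shuffled) == sorted(t.cue for t in sched)
        assert any(a.cue != b.cue for a, b in zip(sched, shuffled))


class TestVectorBins:
    def _pair_table(self, dx):
        rng = np.random.default_rng(4)
        n = 60
        base = np.column_stack([rng.uniform(-5, 5, n), rng.uniform(-5, 5, n)])
        centers = {
            "left": base + [-dx, 0.0],
            "right": base + [dx, 0.0],
            "up": base, "down": base, "distributed": base,
        }
        return _prf_table(centers)

    def test_opposed_shifts_fully_congruent(self):
        bins = binned_shift_vectors(self._pair_table(0.2), pair=("left", "right"))
        assert len(bins) > 0
        assert all(b.congruent for b in bins)

    def test_no_shift_flags_undefined_congruence(self):
        bins = binned_shift_vectors(self._pair_table(0.0), pair=("left", "right"))
        assert all(b.congruent is None for b in bins)

    def test_binning_keys_agree_for_noiseless_data(self):
        table = self._pair_table(0.15)
        a = binned_shift_vectors(table, bin_on="pair_average")
        b = binned_shift_vectors(table, bin_on="distributed")
        assert [(x.ecc_bin, x.angle_bin, x.n_vertices) for x in a] == [
            (x.ecc_bin, x.angle_bin, x.n_vertices) for x in b
        ]

    def test_eccentricity_restricted_below_target(self):
        rng = np.random.default_rng(9)
        base = np.column_stack([rng.uniform(6.5, 10, 30), np.zeros(30)])
        centers = {c: base for c in list(design.FOCAL_CONDITIONS) + ["distributed"]}
        bins = binned_shift_vectors(_prf_table(centers))
        assert bins == []
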