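"""Attention-induced pRF center shifts.

For each vertex and attended target, the change in Euclidean distance from
the pRF center to the target between the focal and distributed conditions is
computed (negative = moved toward the target), averaged over vertices within
a map and over the four attention conditions. A label-shuffled control
re-runs the GLM + pRF stages with permuted cue labels; directional vector
graphs bin paired opposite-condition centers over annulus sectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import FOCAL_CONDITIONS, TrialRecord, build_design_matrix, schedule_n_tr
from .roi import TARGET_ANGLES, cart_to_polar, target_center

__all__ = [
    "ShiftSummary",
    "VectorBin",
    "distance_change_to_target",
    "shuffle_schedule_cues",
    "shuffled_control",
    "binned_shift_vectors",
]


@dataclass
class ShiftSummary:
    """Per-map mean change in pRF-center distance to the attended target."""

    by_map: pd.DataFrame  # map, mean_change (deg), n_vertices
    per_vertex: pd.DataFrame  # vertex, map, change (averaged over targets)
    empty: bool = False


def _condition_pivot(prfs: pd.DataFrame) -> pd.DataFrame:
    """Wide per-vertex table of x, y, r2, eccentricity per condition."""
    return prfs.pivot_table(
        index=["vertex"] + (["map"] if "map" in prfs else []),
        columns="condition",
        values=["x", "y", "r2", "eccentricity"],
    )


def distance_change_to_target(
    prfs: pd.DataFrame,
    targets: dict | None = None,
    ecc_range=(0.5, 5.5),
    min_r2: float = 0.25,
) -> ShiftSummary:
    """Focal-minus-distributed distance to the attended target, per map.

    ``prfs`` is the tidy per-vertex x condition table from
    :func:`anticiprf.prf.fit_population_by_condition` (columns vertex, map,
    condition, x, y, r2, eccentricity). Vertices must satisfy the
    eccentricity range and r2 threshold in *all five* condition models.
    """
    targets = targets or {c: target_center(c) for c in FOCAL_CONDITIONS}
    wide = _condition_pivot(prfs)
    conds = list(FOCAL_CONDITIONS) + ["distributed"]
    ok = np.ones(len(wide), dtype=bool)
    for cond in conds:
        ecc = wide[("eccentricity", cond)].to_numpy()
        r2 = wide[("r2", cond)].to_numpy()
        ok &= (ecc >= ecc_range[0]) & (ecc <= ecc_range[1]) & (r2 > min_r2)
    kept = wide[ok]
    if len(kept) == 0:
        empty = pd.DataFrame(columns=["map", "mean_change", "n_vertices"])
        return ShiftSummary(by_map=empty, per_vertex=pd.DataFrame(), empty=True)

    dx = kept[("x", "distributed")].to_numpy()
    dy = kept[("y", "distributed")].to_numpy()
    changes = np.zeros((len(kept), len(FOCAL_CONDITIONS)))
    for j, cond in enumerate(FOCAL_CONDITIONS):
        tx, ty = targets[cond]
        fx = kept[("x", cond)].to_numpy()
        fy = kept[("y", cond)].to_numpy()
        changes[:, j] = np.hypot(fx - tx, fy - ty) - np.hypot(dx - tx, dy - ty)
    per_vertex = pd.DataFrame(
        {
            "vertex": kept.index.get_level_values("vertex"),
            "change": changes.mean(axis=1),
        }
    )
    if "map" in prfs:
        per_vertex["map"] = kept.index.get_level_values("map")
        by_map = (
            per_vertex.groupby("map", sort=False)["change"]
            .agg(mean_change="mean", n_vertices="size")
            .reset_index()
        )
    else:
        by_map = pd.DataFrame(
            {
                "map": ["all"],
                "mean_change": [per_vertex["change"].mean()],
                "n_vertices": [len(per_vertex)],
            }
        )
    return ShiftSummary(by_map=by_map, per_vertex=per_vertex)


def shuffle_schedule_cues(schedule, seed: int | None):
    """Schedule with attention-cue labels permuted across trials.

    ``seed=None`` applies the identity permutation. Response cues and
    validity are re-derived so each TrialRecord stays internally consistent
    (the GLM ignores them).
    """
    trials = list(schedule)
    cues = [t.cue for t in trials]
    if seed is not None:
        rng = np.random.default_rng(seed)
        cues = [cues[i] for i in rng.permutation(len(cues))]
    out = []
    for t, cue in zip(trials, cues):
        if cue == "distributed":
            validity, resp = "neutral", t.response_cue_location
        else:
            validity = "valid"
            resp = cue
        out.append(
            TrialRecord(
                cue=cue, bar_index=t.bar_index, bar_duration_s=t.bar_duration_s,
                isi_ms=t.isi_ms, response_cue_location=resp, validity=validity,
                onset_tr=t.onset_tr, duration_tr=t.duration_tr,
            )
        )
    return out


def shuffled_control(
    series: np.ndarray,
    schedule,
    apertures,
    seed: int | None,
    map_labels=None,
    hrf=None,
    fit_config=None,
    scan_lengths=None,
    ecc_range=(0.5, 5.5),
    min_r2: float = 0.25,
) -> ShiftSummary:
    """Re-run GLM + per-condition pRF fits with permuted cue labels.

    With ``seed=None`` the identity permutation reproduces the unshuffled
    pipeline result.
    """
    from .glm import fit_glm
    from .prf import fit_population_by_condition

    shuffled = shuffle_schedule_cues(schedule, seed)
    design = build_design_matrix(shuffled, schedule_n_tr(shuffled))
    beta = fit_glm(series, design, hrf=hrf, scan_lengths=scan_lengths)
    profiles = np.nan_to_num(beta.condition_profiles())
    prfs = fit_population_by_condition(
        profiles, apertures, config=fit_config, map_labels=map_labels
    )
    prfs = prfs[prfs["condition"] != "average"]
    return distance_change_to_target(prfs, ecc_range=ecc_range, min_r2=min_r2)


@dataclass
class VectorBin:
    """Mean paired centers of two opposed focal conditions in one sector."""

    ecc_bin: tuple  # (low, high) of the binning annulus, deg
    angle_bin: tuple  # (low, high) polar sector, deg
    center_a: tuple  # mean (x, y) under the first condition of the pair
    center_b: tuple  # mean (x, y) under the second condition
    n_vertices: int
    congruent: bool | None  # None when the paired centers coincide


_PAIR_AXIS = {("left", "right"): 0, ("down", "up"): 1}


def binned_shift_vectors(
    prfs: pd.DataFrame,
    pair=("left", "right"),
    ecc_edges=None,
    angle_step: float = 45.0,
    max_ecc: float = 6.0,
    bin_on: str = "pair_average",
) -> list[VectorBin]:
    """Directional shift vectors over annulus-sector bins.

    Vertices (restricted to pair-averaged eccentricity below the target
    eccentricity) are binned by the eccentricity (0.5-6.25 deg in 1-deg
    steps) and polar angle (45-deg sectors) of their pair-averaged center —
    or of their distributed-condition center with ``bin_on="distributed"``.
    Congruence tests the shift component along the pair's axis: e.g. the
    attend-right mean x must exceed the attend-left mean x.
    """
    key = tuple(sorted(pair))
    if key not in _PAIR_AXIS:
        raise ValueError("pair must be left/right or up/down")
    axis = _PAIR_AXIS[key]
    cond_a, cond_b = key  # ordered so b is the +axis condition (right / up)
    if ecc_edges is None:
        ecc_edges = np.arange(0.5, 6.25 + 0.5, 1.0)

    wide = _condition_pivot(prfs)
    ax = wide[("x", cond_a)].to_numpy()
    ay = wide[("y", cond_a)].to_numpy()
    bx = wide[("x", cond_b)].to_numpy()
    by = wide[("y", cond_b)].to_numpy()
    if bin_on == "pair_average":
        kx, ky = (ax + bx) / 2.0, (ay + by) / 2.0
    elif bin_on == "distributed":
        kx = wide[("x", "distributed")].to_numpy()
        ky = wide[("y", "distributed")].to_numpy()
    else:
        raise ValueError(f"unknown bin_on {bin_on!r}")
    angle, ecc = cart_to_polar(kx, ky)
    keep = ecc < max_ecc

    bins = []
    angle_edges = np.arange(0.0, 360.0 + angle_step / 2, angle_step)
    for i in range(len(ecc_edges) - 1):
        for j in range(len(angle_edges) - 1):
            sel = (
                keep
                & (ecc >= ecc_edges[i]) & (ecc < ecc_edges[i + 1])
                & (angle >= angle_edges[j]) & (angle < angle_edges[j + 1])
            )
            if not np.any(sel):
                continue
            ca = (float(ax[sel].mean()), float(ay[sel].mean()))
            cb = (float(bx[sel].mean()), float(by[sel].mean()))
            if ca == cb:
                congruent = None
            else:
                congruent = bool(cb[axis] > ca[axis])
            bins.append(
                VectorBin(
                    ecc_bin=(float(ecc_edges[i]), float(ecc_edges[i + 1])),
                    angle_bin=(float(angle_edges[j]), float(angle_edges[j + 1])),
                    center_a=ca, center_b=cb,
                    n_vertices=int(sel.sum()), congruent=congruent,
                )
            )
    return bins
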