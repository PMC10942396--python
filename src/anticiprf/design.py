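"""Experimental design: bar apertures, trial schedules, GLM design matrices.

The mapping protocol presents a 3 deg-wide bar aperture at one of 24 vertical
and 24 horizontal positions (plus a blank) inside a 12.4 deg-radius circular
window, while a central pre-cue directs attention to one of the four cardinal
targets or distributes it over all four. The design matrix carries one
indicator column per attention condition x mapping stimulus (5 x 49 = 245)
plus one Gabor-target column per condition (5), i.e. 250 columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "FOCAL_CONDITIONS",
    "N_STIMULI",
    "N_COLUMNS",
    "BLANK_INDEX",
    "ApertureSet",
    "TrialRecord",
    "DesignMatrix",
    "build_bar_apertures",
    "build_trial_schedule",
    "build_design_matrix",
    "mapping_column",
    "target_column",
    "schedule_to_frame",
    "frame_to_schedule",
    "save_schedule_tsv",
    "load_schedule_tsv",
    "save_apertures_h5",
    "load_apertures_h5",
]

#: Attention-condition order used for all condition-indexed arrays and columns.
CONDITIONS = ("up", "down", "left", "right", "distributed")
FOCAL_CONDITIONS = CONDITIONS[:4]
N_STIMULI = 49
BLANK_INDEX = 48
N_COLUMNS = 5 * N_STIMULI + 5  # 245 mapping + 5 target columns

#: Fixed sub-trial event layout in seconds (fixation, pre-cue, ..., see Task).
_FIXATION_S = 0.3
_CUE_S = 0.3
_TARGET_S = 0.1
_POST_TARGET_ISI_S = 0.5
#: TRs appended after the bar offset (ISI + target + response window rounded
#: so that every trial spans an integer number of 1-s TRs).
_TAIL_TR = 3


class InvalidConfigurationError(ValueError):
    """Raised for geometry/probability configurations that cannot be built."""


@dataclass
class ApertureSet:
    """49 binary mapping-stimulus masks on a square visual-field pixel grid.

    Indices 0-23 are vertical bars sweeping left to right, 24-47 horizontal
    bars sweeping bottom to top, 48 is the blank (all-zero) stimulus.
    """

    grid_extent: float  # half-width of the grid, degrees of visual angle
    grid_resolution: int
    apertures: np.ndarray  # (49, R, R) uint8
    orientations: tuple  # per bar: "vertical" | "horizontal"
    bar_offsets: np.ndarray  # signed bar-center position along sweep axis
    bar_width: float = 3.0

    def __post_init__(self):
        self.apertures = np.asarray(self.apertures, dtype=np.uint8)

    @property
    def n_apertures(self) -> int:
        return self.apertures.shape[0]

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate grids (X, Y) in degrees.

        Row 0 is the bottom of the visual field (y = -extent side).
        """
        r = self.grid_resolution
        e = self.grid_extent
        centers = (np.arange(r) + 0.5) / r * 2 * e - e
        return np.meshgrid(centers, centers)

    def flat(self) -> np.ndarray:
        """Apertures as a float (49, R*R) matrix."""
        return self.apertures.reshape(self.n_apertures, -1).astype(float)


def build_bar_apertures(
    width_deg: float = 3.0,
    step_deg: float = 1.0,
    window_radius_deg: float = 12.4,
    resolution: int = 128,
    n_positions: int | None = None,
) -> ApertureSet:
    """Construct the 48 bar apertures plus the blank on a pixel grid.

    A pixel belongs to a bar iff its center lies inside both the bar strip
    (within ``width_deg / 2`` of the bar offset along the sweep axis) and the
    circular window; no anti-aliasing, for bit-reproducibility. The number of
    positions per orientation defaults to ``floor(2 * radius / step)`` (24 at
    the printed geometry), with centers symmetric about zero.
    """
    if width_deg <= 0 or step_deg <= 0 or window_radius_deg <= 0:
        raise InvalidConfigurationError("geometry parameters must be positive")
    if resolution < 32:
        raise InvalidConfigurationError("resolution must be >= 32")
    if n_positions is None:
        n_positions = int(math.floor(2 * window_radius_deg / step_deg))
    if n_positions < 1:
        raise InvalidConfigurationError("no bar positions fit the window")

    offsets = (np.arange(n_positions) - (n_positions - 1) / 2.0) * step_deg
    r = resolution
    centers = (np.arange(r) + 0.5) / r * 2 * window_radius_deg - window_radius_deg
    X, Y = np.meshgrid(centers, centers)
    in_window = X**2 + Y**2 <= window_radius_deg**2

    masks = np.zeros((2 * n_positions + 1, r, r), dtype=np.uint8)
    orientations = []
    half = width_deg / 2.0
    for i, off in enumerate(offsets):  # vertical bars: strip in x
        masks[i] = (np.abs(X - off) <= half) & in_window
        orientations.append("vertical")
    for i, off in enumerate(offsets):  # horizontal bars: strip in y
        masks[n_positions + i] = (np.abs(Y - off) <= half) & in_window
        orientations.append("horizontal")
    orientations.append("blank")

    return ApertureSet(
        grid_extent=window_radius_deg,
        grid_resolution=resolution,
        apertures=masks,
        orientations=tuple(orientations),
        bar_offsets=np.concatenate([offsets, offsets]),
        bar_width=width_deg,
    )


@dataclass
class TrialRecord:
    """One trial of the concurrent psychophysics / pRF-mapping protocol."""

    cue: str  # up | down | left | right | distributed
    bar_index: int  # 0-47 bars, 48 blank
    bar_duration_s: int  # 1 | 2
    isi_ms: int  # 50 | 300 | 400 | 500
    response_cue_location: str  # up | down | left | right
    validity: str  # valid | invalid | neutral
    onset_tr: int
    duration_tr: int

    def __post_init__(self):
        if (self.validity == "neutral") != (self.cue == "distributed"):
            raise ValueError("validity is neutral iff the cue is distributed")
        if self.cue != "distributed":
            expected = "valid" if self.cue == self.response_cue_location else "invalid"
            if self.validity != expected:
                raise ValueError(f"validity {self.validity!r} inconsistent with cue")
        if self.duration_tr <= 0:
            raise ValueError("duration_tr must be a positive integer")

    @property
    def bar_onset_tr(self) -> int:
        """First TR at which the mapping-stimulus indicator is set."""
        return self.onset_tr + 1

    @property
    def target_tr(self) -> int:
        """TR at which the Gabor-target indicator is set."""
        t = _FIXATION_S + _CUE_S + self.bar_duration_s + self.isi_ms / 1000.0
        return self.onset_tr + int(math.floor(t))


_DEFAULT_PROPORTIONS = {
    "cue": {"focal": 0.8, "distributed": 0.2},
    "validity": {"valid": 0.75, "invalid": 0.25},
    "blank": {"blank": 0.1, "bar": 0.9},
    "duration": {1: 0.5, 2: 0.5},
    "isi_ms": {50: 0.1, 300: 0.3, 400: 0.3, 500: 0.3},
}


def build_trial_schedule(
    n_trials: int,
    seed: int,
    proportions: dict | None = None,
    pre_trial_pad_tr: int = 0,
    n_bars: int = 48,
) -> list[TrialRecord]:
    """Sample a seed-reproducible pseudo-random trial schedule.

    Marginal probabilities follow the protocol: focal cues on 80% of trials
    (equiprobable over the four locations), distributed on 20%; focal cues
    75% valid; blank mapping stimulus on 10% of trials; 1-s and 2-s bars;
    jittered ISI of 50 ms (10%) or 300/400/500 ms (30% each). Each family is
    sampled independently per trial. Every trial spans an integer number of
    1-s TRs (bar duration + 3).
    """
    if n_trials <= 0:
        raise InvalidConfigurationError("n_trials must be positive")
    props = dict(_DEFAULT_PROPORTIONS)
    if proportions:
        props.update(proportions)
    for family, table in props.items():
        total = sum(table.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise InvalidConfigurationError(
                f"{family} proportions sum to {total}, expected 1"
            )

    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    onset = pre_trial_pad_tr
    locations = list(FOCAL_CONDITIONS)
    for _ in range(n_trials):
        focal = rng.random() < props["cue"]["focal"]
        if focal:
            cue = locations[rng.integers(4)]
            valid = rng.random() < props["validity"]["valid"]
            if valid:
                response_loc, validity = cue, "valid"
            else:
                others = [loc for loc in locations if loc != cue]
                response_loc, validity = others[rng.integers(3)], "invalid"
        else:
            cue = "distributed"
            response_loc, validity = locations[rng.integers(4)], "neutral"
        if rng.random() < props["blank"]["blank"]:
            bar_index = BLANK_INDEX
        else:
            bar_index = int(rng.integers(n_bars))
        durations = sorted(props["duration"])
        dur = durations[
            int(rng.choice(len(durations), p=[props["duration"][d] for d in durations]))
        ]
        isis = sorted(props["isi_ms"])
        isi = isis[int(rng.choice(len(isis), p=[props["isi_ms"][i] for i in isis]))]
        duration_tr = int(dur) + _TAIL_TR
        trials.append(
            TrialRecord(
                cue=cue,
                bar_index=int(bar_index),
                bar_duration_s=int(dur),
                isi_ms=int(isi),
                response_cue_location=response_loc,
                validity=validity,
                onset_tr=int(onset),
                duration_tr=duration_tr,
            )
        )
        onset += duration_tr
    return trials


def build_balanced_schedule(
    repeats: int = 1,
    seed: int = 0,
    pre_trial_pad_tr: int = 0,
) -> list[TrialRecord]:
    """Schedule covering every condition x stimulus combination equally.

    Simulation-study companion to :func:`build_trial_schedule`: each of the
    5 x 49 condition-stimulus cells occurs exactly ``repeats`` times in
    shuffled order (durations and ISIs still jittered), guaranteeing that
    every mapping regressor of the GLM is estimable from a single session.
    """
    if repeats < 1:
        raise InvalidConfigurationError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    cells = [
        (cond, bar) for cond in CONDITIONS for bar in range(N_STIMULI)
    ] * repeats
    order = rng.permutation(len(cells))
    trials = []
    onset = pre_trial_pad_tr
    locations = list(FOCAL_CONDITIONS)
    isis = (50, 300, 400, 500)
    for k in order:
        cue, bar = cells[k]
        if cue == "distributed":
            validity, resp = "neutral", locations[rng.integers(4)]
        elif rng.random() < 0.75:
            validity, resp = "valid", cue
        else:
            others = [loc for loc in locations if loc != cue]
            validity, resp = "invalid", others[rng.integers(3)]
        dur = int(rng.integers(1, 3))
        trials.append(
            TrialRecord(
                cue=cue, bar_index=int(bar), bar_duration_s=dur,
                isi_ms=int(isis[rng.integers(4)]), response_cue_location=resp,
                validity=validity, onset_tr=int(onset),
                duration_tr=dur + _TAIL_TR,
            )
        )
        onset += dur + _TAIL_TR
    return trials


def schedule_n_tr(schedule: Sequence[TrialRecord]) -> int:
    """Number of TRs spanned by a schedule (last trial offset)."""
    return max(t.onset_tr + t.duration_tr for t in schedule)


def mapping_column(condition: str, bar_index: int) -> int:
    return CONDITIONS.index(condition) * N_STIMULI + bar_index


def target_column(condition: str) -> int:
    return 5 * N_STIMULI + CONDITIONS.index(condition)


@dataclass
class DesignMatrix:
    """TR x 250 indicator matrix with condition x stimulus column labels."""

    values: np.ndarray
    column_labels: tuple

    @property
    def n_tr(self) -> int:
        return self.values.shape[0]


def _column_labels() -> tuple:
    labels = [
        f"map_{cond}_{s:02d}" for cond in CONDITIONS for s in range(N_STIMULI)
    ]
    labels += [f"target_{cond}" for cond in CONDITIONS]
    return tuple(labels)


def build_design_matrix(schedule: Sequence[TrialRecord], n_tr: int) -> DesignMatrix:
    """Build the 250-column indicator design matrix for a schedule.

    The mapping indicator is 1 for the 1 or 2 TRs the bar is shown, under the
    trial's condition x bar column; the Gabor-target indicator is a single 1
    at the target TR under the trial's condition column.
    """
    X = np.zeros((n_tr, N_COLUMNS))
    for trial in schedule:
        end = trial.onset_tr + trial.duration_tr
        if trial.onset_tr < 0 or end > n_tr:
            raise IndexError(
                f"trial at onset_tr={trial.onset_tr} exceeds scan length {n_tr}"
            )
        col = mapping_column(trial.cue, trial.bar_index)
        X[trial.bar_onset_tr : trial.bar_onset_tr + trial.bar_duration_s, col] = 1.0
        X[trial.target_tr, target_column(trial.cue)] = 1.0
    return DesignMatrix(values=X, column_labels=_column_labels())


# ---------------------------------------------------------------------------
# serialization

_SCHEDULE_COLUMNS = [
    "cue",
    "bar_index",
    "bar_duration_s",
    "isi_ms",
    "response_cue_location",
    "validity",
    "onset_tr",
    "duration_tr",
]


def schedule_to_frame(schedule: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in schedule], columns=_SCHEDULE_COLUMNS)


def frame_to_schedule(frame: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(**{k: row[k] for k in _SCHEDULE_COLUMNS})
        for _, row in frame.astype(
            {c: int for c in ("bar_index", "bar_duration_s", "isi_ms", "onset_tr", "duration_tr")}
        ).iterrows()
    ]


def save_schedule_tsv(schedule: Sequence[TrialRecord], path) -> None:
    """Write one row per trial; TR indices are 0-based (see column header)."""
    with open(path, "w") as fh:
        fh.write("# onset_tr/duration_tr are 0-based TR indices (TR = 1 s)\n")
        schedule_to_frame(schedule).to_csv(fh, sep="\t", index=False)


def load_schedule_tsv(path) -> list[TrialRecord]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return frame_to_schedule(frame)


def save_apertures_h5(apertures: ApertureSet, h5_path, json_path=None) -> None:
    import h5py

    with h5py.File(h5_path, "w") as fh:
        fh.create_dataset("apertures", data=apertures.apertures, dtype="uint8")
    meta = {
        "grid_extent": apertures.grid_extent,
        "grid_resolution": apertures.grid_resolution,
        "bar_width": apertures.bar_width,
        "orientations": list(apertures.orientations),
        "bar_offsets": [float(v) for v in apertures.bar_offsets],
    }
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def load_apertures_h5(h5_path, json_path) -> ApertureSet:
    import h5py

    with h5py.File(h5_path, "r") as fh:
        masks = fh["apertures"][()]
    with open(json_path) as fh:
        meta = json.load(fh)
    return ApertureSet(
        grid_extent=meta["grid_extent"],
        grid_resolution=meta["grid_resolution"],
        apertures=masks,
        orientations=tuple(meta["orientations"]),
        bar_offsets=np.asarray(meta["bar_offsets"]),
        bar_width=meta["bar_width"],
    )
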