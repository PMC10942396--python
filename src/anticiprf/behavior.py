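"""Behavioral sensitivity, bootstrap confidence intervals, gaze statistics.

Sensitivity follows the equal-variance signal-detection convention for a
2AFC tilt judgment: clockwise is arbitrarily "target present", so
d' = z(hit rate) - z(false-alarm rate), with a 0.5 correction applied to the
hit and false-alarm counts before computing rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .roi import TARGET_ANGLES

__all__ = [
    "DISPLAY",
    "DisplayGeometry",
    "px_to_deg",
    "deg_to_px",
    "compute_dprime",
    "dprime_table",
    "bootstrap_group",
    "GazeSummary",
    "analyze_gaze",
]


@dataclass(frozen=True)
class DisplayGeometry:
    """Scanner display: projected screen size, resolution, viewing distance."""

    width_px: int = 1920
    height_px: int = 1080
    width_cm: float = 60.0
    height_cm: float = 36.2
    distance_cm: float = 86.5

    @property
    def cm_per_px(self) -> tuple:
        return (self.width_cm / self.width_px, self.height_cm / self.height_px)


DISPLAY = DisplayGeometry()


def px_to_deg(x_px, y_px, display: DisplayGeometry = DISPLAY):
    """Screen pixels (origin top-left, y down) to visual degrees (y up)."""
    cx, cy = display.width_px / 2.0, display.height_px / 2.0
    sx, sy = display.cm_per_px
    x = np.degrees(np.arctan((np.asarray(x_px, dtype=float) - cx) * sx / display.distance_cm))
    y = np.degrees(np.arctan((cy - np.asarray(y_px, dtype=float)) * sy / display.distance_cm))
    return x, y


def deg_to_px(x_deg, y_deg, display: DisplayGeometry = DISPLAY):
    """Inverse of :func:`px_to_deg`."""
    cx, cy = display.width_px / 2.0, display.height_px / 2.0
    sx, sy = display.cm_per_px
    x = cx + np.tan(np.radians(np.asarray(x_deg, dtype=float))) * display.distance_cm / sx
    y = cy - np.tan(np.radians(np.asarray(y_deg, dtype=float))) * display.distance_cm / sy
    return x, y


def compute_dprime(tilt_cw, response_cw, correction: str = "loglinear"):
    """Equal-variance d' for one validity x location cell.

    ``tilt_cw`` and ``response_cw`` are boolean arrays (truth and report).
    Hits are CW responses on CW-tilt trials; false alarms CW responses on
    CCW-tilt trials. The default log-linear correction adds 0.5 to the hit
    and false-alarm counts and 1.0 to the corresponding trial counts;
    ``correction="numerator"`` adds 0.5 to the counts only. Empty cells (no
    CW-true or no CCW-true trials) return NaN.
    """
    tilt_cw = np.asarray(tilt_cw, dtype=bool)
    response_cw = np.asarray(response_cw, dtype=bool)
    n_signal = int(tilt_cw.sum())
    n_noise = int((~tilt_cw).sum())
    if n_signal == 0 or n_noise == 0:
        return float("nan")
    hits = int((tilt_cw & response_cw).sum())
    fas = int((~tilt_cw & response_cw).sum())
    if correction == "loglinear":
        hr = (hits + 0.5) / (n_signal + 1.0)
        far = (fas + 0.5) / (n_noise + 1.0)
    elif correction == "numerator":
        hr = min((hits + 0.5) / n_signal, 1.0 - 1e-12)
        far = min((fas + 0.5) / n_noise, 1.0 - 1e-12)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def dprime_table(trials: pd.DataFrame, correction: str = "loglinear") -> pd.DataFrame:
    """d' and mean RT per validity x response-cue-location cell.

    ``trials`` needs columns validity, response_cue_location, tilt_cw,
    response_cw and (optionally) rt_s. RTs are averaged over correct and
    incorrect trials alike.
    """
    records = []
    for (validity, loc), cell in trials.groupby(
        ["validity", "response_cue_location"], sort=False
    ):
        rec = {
            "validity": validity,
            "location": loc,
            "d_prime": compute_dprime(cell["tilt_cw"], cell["response_cw"], correction),
            "n_trials": len(cell),
        }
        if "rt_s" in cell:
            rec["mean_rt_s"] = float(cell["rt_s"].mean())
        records.append(rec)
    return pd.DataFrame(records)


def bootstrap_group(values, n_boot: int = 1000, ci: float = 68.0, seed: int = 0):
    """Percentile CI of the resampled group mean (participants as units)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(means, [half, 100.0 - half])
    return float(values.mean()), (float(lo), float(hi))


@dataclass
class GazeSummary:
    """Median corrected gaze per cue type and fixation-break statistics."""

    by_cue: pd.DataFrame  # cue, x_deg, y_deg (median corrected), n_trials
    fixation_break_fraction: float  # fraction of samples beyond 2 deg
    n_excluded_trials: int = 0  # all-blink analysis windows


def analyze_gaze(
    samples: pd.DataFrame,
    schedule,
    display: DisplayGeometry = DISPLAY,
    break_criterion_deg: float = 2.0,
) -> GazeSummary:
    """Per-cue gaze statistics from 1 kHz samples.

    ``samples`` needs columns t_ms, x_px, y_px, blink. For each trial the
    mean gaze over the window from mapping-stimulus onset to target onset is
    computed (blink samples removed); per-cue means are corrected by
    subtracting the median gaze over the 300-ms fixation periods. The
    fixation-break fraction counts in-trial non-blink samples whose
    eccentricity exceeds ``break_criterion_deg``.
    """
    t = samples["t_ms"].to_numpy()
    gx, gy = px_to_deg(samples["x_px"].to_numpy(), samples["y_px"].to_numpy(), display)
    blink = samples["blink"].to_numpy(dtype=bool)

    trial_means, fix_samples, cue_labels = [], [], []
    n_excluded = 0
    n_break = 0
    n_in_trial = 0
    for trial in schedule:
        t0 = trial.onset_tr * 1000.0
        bar_on = t0 + 600.0
        target_on = bar_on + trial.bar_duration_s * 1000.0 + trial.isi_ms
        trial_end = t0 + trial.duration_tr * 1000.0

        in_trial = (t >= t0) & (t < trial_end) & ~blink
        n_in_trial += int(in_trial.sum())
        n_break += int((np.hypot(gx[in_trial], gy[in_trial]) > break_criterion_deg).sum())

        fix = (t >= t0) & (t < t0 + 300.0) & ~blink
        if np.any(fix):
            fix_samples.append(np.column_stack([gx[fix], gy[fix]]))
        win = (t >= bar_on) & (t < target_on) & ~blink
        if not np.any(win):
            n_excluded += 1
            continue
        trial_means.append((gx[win].mean(), gy[win].mean()))
        cue_labels.append(trial.cue)

    if not trial_means:
        raise ValueError("no analyzable trials in the gaze record")
    fix_all = np.vstack(fix_samples) if fix_samples else np.zeros((1, 2))
    fix_median = np.median(fix_all, axis=0)
    means = np.asarray(trial_means) - fix_median

    frame = pd.DataFrame({"cue": cue_labels, "x_deg": means[:, 0], "y_deg": means[:, 1]})
    by_cue = (
        frame.groupby("cue", sort=False)
        .agg(x_deg=("x_deg", "median"), y_deg=("y_deg", "median"), n_trials=("x_deg", "size"))
        .reset_index()
    )
    frac = n_break / n_in_trial if n_in_trial else float("nan")
    return GazeSummary(by_cue=by_cue, fixation_break_fraction=float(frac),
                       n_excluded_trials=n_excluded)
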