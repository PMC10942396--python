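"""Ground-truth simulator: vertex populations, attention-modulated responses,
noisy BOLD time series, SDT behavior, and fixational gaze.

Every downstream stage of the pipeline is validated by parameter recovery
against the quantities generated here: true pRFs (x0, y0, sigma0), known
additive baseline shifts, attention-field-induced center shifts, generating
d' values, and injected gaze biases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as _behavior
from .design import (
    CONDITIONS,
    FOCAL_CONDITIONS,
    N_STIMULI,
    ApertureSet,
    TrialRecord,
    build_design_matrix,
    schedule_n_tr,
)
from .glm import HemodynamicResponse, double_gamma_hrf, convolve_with_hrf
from .roi import TARGET_ANGLES, cart_to_polar, polar_angle_distance, target_center
from .tuning import diff_von_mises

__all__ = [
    "MAPS",
    "DEFAULT_SIZE_SLOPES",
    "GroundTruthVertex",
    "AttentionFieldSpec",
    "ModulationSpec",
    "NoiseSpec",
    "sample_prf_population",
    "attention_field_transform",
    "shifted_center",
    "apply_attention",
    "gaussian_overlap",
    "simulate_beta_truth",
    "simulate_bold",
    "simulate_behavior",
    "simulate_gaze",
]

MAPS = ("V1", "V2", "V3", "hV4", "V3A/B", "LO1")

#: pRF size vs eccentricity slopes per map (deg size per deg eccentricity),
#: increasing along the cortical hierarchy as retinotopy studies report.
DEFAULT_SIZE_SLOPES = {
    "V1": 0.10, "V2": 0.15, "V3": 0.20, "hV4": 0.35, "V3A/B": 0.30, "LO1": 0.40,
}
DEFAULT_SIZE_INTERCEPT = 0.5


@dataclass
class GroundTruthVertex:
    """A synthetic vertex with known pRF and attentional modulation.

    ``cond_prfs`` maps each attention condition to the effective
    (x, y, sigma); ``b_add`` to the additive baseline shift in %BOLD;
    ``gain_mod`` to a multiplicative response-gain factor (1 = none).
    """

    map_label: str
    x0: float
    y0: float
    sigma0: float
    gain: float = 1.0
    cond_prfs: dict = field(default_factory=dict)
    b_add: dict = field(default_factory=dict)
    gain_mod: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        for cond in CONDITIONS:
            self.cond_prfs.setdefault(cond, (self.x0, self.y0, self.sigma0))
            self.b_add.setdefault(cond, 0.0)
            self.gain_mod.setdefault(cond, 1.0)

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))


@dataclass
class AttentionFieldSpec:
    """Gaussian attention field per focal condition.

    Targets default to 6 deg eccentricity on the cardinal meridians. ``mode``
    selects what the field does to the responses: an additive baseline shift
    only, a pRF position shift only, both, or a multiplicative response gain.
    """

    sigma_attn: float = 4.0
    mode: str = "both"  # additive_only | position_only | both | multiplicative_gain
    target_centers: dict = field(
        default_factory=lambda: {c: target_center(c) for c in FOCAL_CONDITIONS}
    )
    shrink_sigma: bool = False  # apply the Gaussian-product sigma as well

    def __post_init__(self):
        if self.sigma_attn <= 0:
            raise ValueError("sigma_attn must be positive")
        if self.mode not in {"additive_only", "position_only", "both", "multiplicative_gain"}:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ModulationSpec:
    """Wedge-shaped additive modulation profile and its temporal account.

    The additive baseline shift of a vertex under a focal cue is the
    difference-of-von-Mises profile evaluated at the polar-angle distance
    between the vertex's pRF and the attended target. Defaults give a peak
    enhancement of ~0.09 %BOLD and a far-target suppression of ~-0.04 %BOLD.
    The temporal account positions the modulation within the trial:
    ``transient`` (1 s after cue), ``sustained`` (cue TR through target TR),
    or ``target_evoked`` (target TR onward).
    """

    S: float = 0.2
    B: float = -0.03
    mu: float = 0.0
    kappa1: float = 6.0
    kappa2: float = 1.0
    account: str = "sustained"

    def __post_init__(self):
        if self.account not in {"sustained", "transient", "target_evoked"}:
            raise ValueError(f"unknown account {self.account!r}")

    def profile(self, polar_distance_deg):
        return diff_von_mises(polar_distance_deg, self.S, self.B, self.mu,
                              self.kappa1, self.kappa2)


@dataclass
class NoiseSpec:
    """Additive noise on the %BOLD scale: white Gaussian plus slow drift."""

    white_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_order: int = 1

    def __post_init__(self):
        if self.white_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise SDs must be >= 0")


def sample_prf_population(
    n_per_map: int,
    size_ecc_slopes: dict | None = None,
    seed: int = 0,
    size_intercept: float = DEFAULT_SIZE_INTERCEPT,
    sigma_jitter_sd: float = 0.1,
    field_radius: float = 12.4,
    gain_range=(0.8, 1.5),
) -> list[GroundTruthVertex]:
    """Sample vertices with quasi-uniform centers and linear size-ecc scaling.

    Centers are uniform over the disk of ``field_radius``; sizes follow
    sigma0 = intercept + slope(map) * eccentricity + Gaussian jitter,
    truncated positive; gains are uniform over ``gain_range``.
    """
    if n_per_map <= 0:
        raise ValueError("n_per_map must be positive")
    slopes = size_ecc_slopes or DEFAULT_SIZE_SLOPES
    if any(s <= 0 for s in slopes.values()):
        raise ValueError("size-eccentricity slopes must be positive")
    rng = np.random.default_rng(seed)
    vertices = []
    for map_label, slope in slopes.items():
        r = field_radius * np.sqrt(rng.random(n_per_map))
        theta = rng.random(n_per_map) * 2 * np.pi
        x, y = r * np.cos(theta), r * np.sin(theta)
        sigma = size_intercept + slope * r + rng.normal(0, sigma_jitter_sd, n_per_map)
        sigma = np.maximum(sigma, 0.05)
        gains = rng.uniform(*gain_range, n_per_map)
        for i in range(n_per_map):
            vertices.append(
                GroundTruthVertex(
                    map_label=map_label, x0=float(x[i]), y0=float(y[i]),
                    sigma0=float(sigma[i]), gain=float(gains[i]),
                )
            )
    return vertices


def attention_field_transform(prf, attn_field):
    """Gaussian-product pRF under an attention field (closed form).

    With pRF (x0, y0, sigma0) and field (xa, ya, sigma_attn), the product of
    the two Gaussians is a Gaussian with

        center = (sigma_attn^2 * prf_center + sigma0^2 * field_center)
                 / (sigma0^2 + sigma_attn^2)   (componentwise)
        sigma  = sqrt(sigma0^2 * sigma_attn^2 / (sigma0^2 + sigma_attn^2))

    so the center moves toward the attended location and the size shrinks
    below both inputs.
    """
    x0, y0, s0 = prf
    xa, ya, sa = attn_field
    if s0 <= 0 or sa <= 0:
        raise ValueError("sigmas must be positive")
    w = s0**2 + sa**2
    xc = (sa**2 * x0 + s0**2 * xa) / w
    yc = (sa**2 * y0 + s0**2 * ya) / w
    sc = math.sqrt(s0**2 * sa**2 / w)
    return (xc, yc, sc)


def shifted_center(center, target, magnitude: float):
    """Center displaced ``magnitude`` degrees along the line to ``target``."""
    cx, cy = center
    tx, ty = target
    d = math.hypot(tx - cx, ty - cy)
    if d == 0:
        return (cx, cy)
    f = magnitude / d
    return (cx + f * (tx - cx), cy + f * (ty - cy))


def apply_attention(
    vertices,
    attn: AttentionFieldSpec,
    mod: ModulationSpec | None = None,
) -> list[GroundTruthVertex]:
    """Fill per-condition effective pRFs, baseline shifts, and gain factors.

    Position shifts use the Gaussian-product closed form (center always;
    sigma only if ``attn.shrink_sigma``). Additive shifts and gain factors
    evaluate the wedge profile at each vertex's polar-angle distance to the
    attended target. Modifies and returns the vertex list.
    """
    mod = mod or ModulationSpec()
    for v in vertices:
        angle, _ = cart_to_polar(v.x0, v.y0)
        for cond in FOCAL_CONDITIONS:
            tx, ty = attn.target_centers[cond]
            dist = polar_angle_distance(angle, TARGET_ANGLES[cond])
            if attn.mode in {"position_only", "both"}:
                xc, yc, sc = attention_field_transform(
                    (v.x0, v.y0, v.sigma0), (tx, ty, attn.sigma_attn)
                )
                v.cond_prfs[cond] = (xc, yc, sc if attn.shrink_sigma else v.sigma0)
            else:
                v.cond_prfs[cond] = (v.x0, v.y0, v.sigma0)
            v.b_add[cond] = (
                float(mod.profile(dist))
                if attn.mode in {"additive_only", "both"} else 0.0
            )
            v.gain_mod[cond] = (
                1.0 + float(mod.profile(dist))
                if attn.mode == "multiplicative_gain" else 1.0
            )
        v.cond_prfs["distributed"] = (v.x0, v.y0, v.sigma0)
        v.b_add["distributed"] = 0.0
        v.gain_mod["distributed"] = 1.0
    return vertices


def gaussian_overlap(center_sigma, apertures: ApertureSet) -> np.ndarray:
    """Normalized overlap of a unit-peak Gaussian with every aperture."""
    from .prf import _gaussian_overlaps

    x, y, s = center_sigma
    return _gaussian_overlaps(apertures, x, y, s)[0]


def simulate_beta_truth(vertices, apertures: ApertureSet) -> np.ndarray:
    """True per-condition beta profiles, (n_vertices, 5, 49) in %BOLD.

    beta[c, s] = gain_mod[c] * gain * overlap(effective Gaussian_c, s)
                 + b_add[c]; the blank stimulus has zero overlap so it
    receives the additive term only.
    """
    betas = np.zeros((len(vertices), 5, N_STIMULI))
    for i, v in enumerate(vertices):
        for ci, cond in enumerate(CONDITIONS):
            ov = gaussian_overlap(v.cond_prfs[cond], apertures)
            betas[i, ci] = v.gain_mod[cond] * v.gain * ov + v.b_add[cond]
    return betas


def _modulation_trs(trial: TrialRecord, account: str):
    if account == "transient":
        return range(trial.onset_tr, trial.onset_tr + 1)
    if account == "sustained":
        return range(trial.onset_tr, trial.target_tr + 1)
    if account == "target_evoked":
        return range(trial.target_tr, trial.onset_tr + trial.duration_tr)
    raise ValueError(f"unknown account {account!r}")


def simulate_bold(
    beta_profiles: np.ndarray,
    schedule,
    hrf: HemodynamicResponse | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    target_betas=1.0,
    modulation=None,
    account: str = "sustained",
    n_tr: int | None = None,
    scan_lengths=None,
    baseline: float = 1000.0,
) -> np.ndarray:
    """Per-vertex raw BOLD series from true betas and a trial schedule.

    The neural predictor is the indicator design times the true betas
    (boxcar over the bar TRs, transient at the target TR), optionally plus a
    per-trial additive-modulation boxcar placed by the temporal ``account``
    (``modulation`` is (n_vertices, 5) %BOLD values per condition; pass it
    only with beta profiles that exclude the additive term). The predictor
    is HRF-convolved per scan, drift and white noise are added on the %BOLD
    scale, and the series is baseline * (1 + x / 100).
    """
    B = np.asarray(beta_profiles, dtype=float)
    n_v = B.shape[0]
    hrf = hrf or double_gamma_hrf()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    if n_tr is None:
        n_tr = schedule_n_tr(schedule)
    if scan_lengths is None:
        scan_lengths = [n_tr]
    design = build_design_matrix(schedule, n_tr)
    D_map = design.values[:, : 5 * N_STIMULI]
    D_tgt = design.values[:, 5 * N_STIMULI :]

    tb = np.asarray(target_betas, dtype=float)
    if tb.ndim == 0:
        tb = np.full((n_v, 5), float(tb))
    neural = D_map @ B.reshape(n_v, -1).T + D_tgt @ tb.T  # (n_tr, n_v)

    if modulation is not None:
        M = np.asarray(modulation, dtype=float)
        for trial in schedule:
            ci = CONDITIONS.index(trial.cue)
            for tr in _modulation_trs(trial, account):
                if tr < n_tr:
                    neural[tr] += M[:, ci]

    conv = np.zeros_like(neural)
    start = 0
    for length in scan_lengths:
        for j in range(n_v):
            conv[start : start + length, j] = convolve_with_hrf(
                neural[start : start + length, j], hrf
            )
        start += length

    pct = conv.T  # (n_v, n_tr)
    if noise.drift_amplitude > 0:
        start = 0
        for length in scan_lengths:
            t = np.linspace(-1, 1, length)
            for k in range(1, noise.drift_order + 1):
                coefs = rng.uniform(-noise.drift_amplitude, noise.drift_amplitude, n_v)
                pct[:, start : start + length] += coefs[:, None] * t[None, :] ** k
            start += length
    if noise.white_sd > 0:
        pct = pct + rng.normal(0, noise.white_sd, pct.shape)
    return baseline * (1.0 + pct / 100.0)


_DEFAULT_DPRIME = {"valid": 4.0, "neutral": 1.6, "invalid": 0.5}
_DEFAULT_RT_MEAN = {"valid": 0.30, "neutral": 0.56, "invalid": 0.56}


def simulate_behavior(
    schedule,
    dprime_by_validity: dict | None = None,
    rt_mean_by_validity: dict | None = None,
    rt_shift: float = 0.1,
    rt_sigma: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Equal-variance SDT responses and shifted-lognormal RTs per trial.

    The true tilt is CW or CCW with equal probability; internal evidence is
    Normal(+/- d'/2, 1) with criterion 0, so the long-run accuracy of a cell
    is Phi(d'/2). Default d' values are the group means the protocol is
    calibrated to (valid 4.0, neutral 1.6, invalid 0.5); RT locations give
    mean 0.30 s on valid and 0.56 s on neutral/invalid trials.
    """
    dmap = dprime_by_validity or _DEFAULT_DPRIME
    rmap = rt_mean_by_validity or _DEFAULT_RT_MEAN
    if any(d < 0 for d in dmap.values()):
        raise ValueError("d' values must be >= 0")
    rng = np.random.default_rng(seed)
    from .design import schedule_to_frame

    frame = schedule_to_frame(schedule)
    n = len(frame)
    tilt_cw = rng.random(n) < 0.5
    d = frame["validity"].map(dmap).to_numpy(dtype=float)
    evidence = rng.normal(np.where(tilt_cw, d / 2.0, -d / 2.0), 1.0)
    response_cw = evidence > 0
    rt_target = frame["validity"].map(rmap).to_numpy(dtype=float)
    mu = np.log(np.maximum(rt_target - rt_shift, 1e-3)) - rt_sigma**2 / 2.0
    rt = rt_shift + rng.lognormal(mu, rt_sigma)
    frame["tilt_cw"] = tilt_cw
    frame["response_cw"] = response_cw
    frame["correct"] = tilt_cw == response_cw
    frame["rt_s"] = rt
    return frame


def simulate_gaze(
    schedule,
    fixation_sd_deg: float = 0.15,
    blink_rate: float = 0.02,
    bias_deg=(0.0, 0.0),
    seed: int = 0,
    sample_rate_hz: int = 1000,
    display: _behavior.DisplayGeometry = _behavior.DISPLAY,
) -> pd.DataFrame:
    """1 kHz gaze samples around central fixation with blink gaps.

    Gaze jitters around fixation plus an optional bias (degrees); blinks are
    drawn in 100-ms episodes with probability ``blink_rate`` per episode, so
    the flagged sample fraction converges to ``blink_rate``.
    """
    if fixation_sd_deg < 0 or blink_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    n_tr = schedule_n_tr(schedule)
    n = n_tr * sample_rate_hz
    t_ms = np.arange(n) * (1000.0 / sample_rate_hz)
    gx = bias_deg[0] + rng.normal(0, fixation_sd_deg, n)
    gy = bias_deg[1] + rng.normal(0, fixation_sd_deg, n)
    x_px, y_px = _behavior.deg_to_px(gx, gy, display)

    block = sample_rate_hz // 10  # 100-ms blink episodes
    n_blocks = math.ceil(n / block)
    blink_blocks = rng.random(n_blocks) < blink_rate
    blink = np.repeat(blink_blocks, block)[:n]
    return pd.DataFrame({"t_ms": t_ms, "x_px": x_px, "y_px": y_px, "blink": blink})
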