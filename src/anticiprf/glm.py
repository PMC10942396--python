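"""Event-related GLM on vertex BOLD time series.

Each vertex's series is modeled as the HRF-convolved 250-column indicator
design plus per-scan polynomial nuisance regressors, solved by ordinary least
squares. Betas are converted to %BOLD by dividing by the vertex's mean signal
intensity and multiplying by 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import DesignMatrix, N_STIMULI, N_COLUMNS

__all__ = [
    "HemodynamicResponse",
    "double_gamma_hrf",
    "convolve_with_hrf",
    "NuisanceSpec",
    "BetaProfile",
    "fit_glm",
    "smooth_sweep",
    "smooth_beta_profile",
]


class DegenerateDesignError(ValueError):
    """Raised when the augmented design is rank-deficient."""


@dataclass
class HemodynamicResponse:
    """Sampled hemodynamic impulse response (1-s sampling, 50-s support)."""

    values: np.ndarray
    dt: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def peak_time(self) -> float:
        return float(np.argmax(self.values) * self.dt)


def double_gamma_hrf(duration_s: float = 50.0, dt: float = 1.0,
                     peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     undershoot_ratio: float = 6.0) -> HemodynamicResponse:
    """Canonical double-gamma HRF (positive lobe peaking near 5 s).

    h(t) = Gamma(peak_delay, 1).pdf(t) - Gamma(undershoot_delay, 1).pdf(t) /
    undershoot_ratio, normalized to unit peak. With the default shape
    parameters the positive lobe peaks at ~5 s.
    """
    t = np.arange(0.0, duration_s, dt)
    h = stats.gamma.pdf(t, peak_delay) - stats.gamma.pdf(t, undershoot_delay) / undershoot_ratio
    return HemodynamicResponse(values=h / h.max(), dt=dt)


def convolve_with_hrf(column: np.ndarray, hrf: HemodynamicResponse) -> np.ndarray:
    """Causal discrete convolution with the HRF, truncated to series length."""
    if not np.isclose(hrf.dt, 1.0):
        raise ValueError("HRF must be sampled at the 1-s TR grid")
    column = np.asarray(column, dtype=float)
    return np.convolve(column, hrf.values)[: column.shape[0]]


def _convolve_design(values: np.ndarray, hrf: HemodynamicResponse,
                     scan_lengths) -> np.ndarray:
    """HRF-convolve every column, independently within each scan block."""
    out = np.zeros_like(values, dtype=float)
    start = 0
    for length in scan_lengths:
        block = values[start : start + length]
        conv = np.apply_along_axis(lambda c: convolve_with_hrf(c, hrf), 0, block)
        out[start : start + length] = conv
        start += length
    return out


@dataclass
class NuisanceSpec:
    """Per-scan polynomial detrending order (>= 0)."""

    poly_order: int = 2

    def __post_init__(self):
        if self.poly_order < 0:
            raise ValueError("polynomial order must be >= 0")


def _nuisance_matrix(scan_lengths, order: int) -> np.ndarray:
    """Block-diagonal Legendre polynomials, one block per scan."""
    n_tr = int(sum(scan_lengths))
    cols = []
    start = 0
    for length in scan_lengths:
        t = np.linspace(-1.0, 1.0, length)
        for k in range(order + 1):
            col = np.zeros(n_tr)
            col[start : start + length] = np.polynomial.legendre.Legendre.basis(k)(t)
            cols.append(col)
        start += length
    return np.column_stack(cols)


@dataclass
class BetaProfile:
    """Per-vertex GLM solution in %BOLD.

    ``betas`` is (n_vertices, 250); columns whose regressor never occurred in
    the schedule are NaN. ``var_explained`` is the fraction of detrended
    variance captured by the task regressors.
    """

    betas: np.ndarray
    column_labels: tuple
    var_explained: np.ndarray
    mean_signal: np.ndarray
    active_columns: np.ndarray

    def condition_profiles(self) -> np.ndarray:
        """Mapping betas reshaped to (n_vertices, 5 conditions, 49 stimuli)."""
        return self.betas[:, : 5 * N_STIMULI].reshape(-1, 5, N_STIMULI)

    def target_betas(self) -> np.ndarray:
        return self.betas[:, 5 * N_STIMULI :]


def fit_glm(
    series: np.ndarray,
    design: DesignMatrix,
    hrf: HemodynamicResponse | None = None,
    nuisance: NuisanceSpec | None = None,
    scan_lengths=None,
) -> BetaProfile:
    """OLS fit of the convolved indicator design to raw vertex time series.

    Parameters
    ----------
    series : (n_vertices, n_tr) raw signal (arbitrary units; %BOLD conversion
        divides by each vertex's temporal mean).
    design : the 250-column indicator matrix.
    scan_lengths : TR counts per scan for the per-scan nuisance blocks and
        convolution boundaries; a single concatenated scan by default.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    hrf = hrf or double_gamma_hrf()
    nuisance = nuisance or NuisanceSpec()
    n_tr = design.n_tr
    if series.shape[1] != n_tr:
        raise ValueError("series length does not match design")
    if scan_lengths is None:
        scan_lengths = [n_tr]
    if sum(scan_lengths) != n_tr:
        raise ValueError("scan_lengths do not sum to the series length")

    X_task = _convolve_design(design.values, hrf, scan_lengths)
    active = np.flatnonzero(np.any(design.values != 0, axis=0))
    N = _nuisance_matrix(scan_lengths, nuisance.poly_order)
    X = np.hstack([X_task[:, active], N])

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the R diagonal of a pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = piv[diag < diag.max() * 1e-10]
        labels = [
            design.column_labels[active[i]] if i < active.size else f"nuisance_{i - active.size}"
            for i in sorted(bad)
        ]
        raise DegenerateDesignError(f"design is rank deficient; collinear columns: {labels}")

    Y = series.T  # (n_tr, n_vertices)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    resid = Y - fitted

    # variance explained by the task regressors beyond the nuisance space
    coef_n, *_ = np.linalg.lstsq(N, Y, rcond=None)
    resid_n = Y - N @ coef_n
    tss = np.sum(resid_n**2, axis=0)
    rss = np.sum(resid**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ve = np.where(tss > 0, 1.0 - rss / tss, 0.0)

    mean_signal = series.mean(axis=1)
    if np.any(mean_signal == 0):
        raise ValueError("vertex with zero mean signal; cannot convert to %BOLD")
    betas = np.full((series.shape[0], N_COLUMNS), np.nan)
    betas[:, active] = (coef[: active.size] / mean_signal[None, :] * 100.0).T
    return BetaProfile(
        betas=betas,
        column_labels=design.column_labels,
        var_explained=ve,
        mean_signal=mean_signal,
        active_columns=active,
    )


def _triangular_kernel(width: int) -> np.ndarray:
    if width < 1 or width % 2 == 0:
        raise ValueError("kernel width must be a positive odd integer")
    half = width // 2
    k = np.concatenate([np.arange(1, half + 2), np.arange(half, 0, -1)]).astype(float)
    return k / k.sum()


def smooth_sweep(values: np.ndarray, width: int = 3) -> np.ndarray:
    """Edge-padded triangular smoothing of one bar sweep (visualization only)."""
    values = np.asarray(values, dtype=float)
    kernel = _triangular_kernel(width)
    half = width // 2
    padded = np.concatenate([np.full(half, values[0]), values, np.full(half, values[-1])])
    return np.convolve(padded, kernel, mode="valid")


def smooth_beta_profile(betas: np.ndarray, width: int = 3) -> np.ndarray:
    """Smooth a 48-bar profile within each sweep independently.

    Input is ordered as one sweep followed by the other (24 + 24 bars, blank
    excluded). Never feeds the pRF fit.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape[0] % 2 != 0:
        raise ValueError("expected an even number of bar betas (two sweeps)")
    half = betas.shape[0] // 2
    return np.concatenate([smooth_sweep(betas[:half], width), smooth_sweep(betas[half:], width)])
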