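"""Spatial profile of anticipatory amplitude modulation.

Vertices' focal-minus-distributed response changes (averaged over the 49
mapping stimuli) are projected into visual space, collapsed to polar-angle
tuning curves in 20-degree bins, and summarized with a difference of two von
Mises functions

    y(x) = V(x; mu, kappa1) - V(x; mu, kappa2) + B,
    V(x; mu, kappa) = S * exp(kappa * cos(x - mu)) / (2 * pi * I0(kappa)),

whose x-intercepts mark the transition from attentional enhancement to
suppression (the attentional spread). Polar-angle distances in degrees map
linearly onto [-pi, pi] so the von Mises period matches the polar circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, interpolate
from sklearn.base import BaseEstimator

from .roi import polar_angle_distance, cart_to_polar

__all__ = [
    "diff_von_mises",
    "VonMisesParams",
    "TuningCurve",
    "SpreadEstimate",
    "modulation_2d_map",
    "polar_tuning_curve",
    "DiffVonMisesModel",
    "fit_diff_von_mises",
    "attentional_spread",
]


def diff_von_mises(x_deg, S, B, mu_deg, kappa1, kappa2, S2=None):
    """Difference-of-von-Mises profile evaluated at polar distances (deg).

    With ``S2`` unset the scalar S is shared between the two terms (default
    reading of the model); pass ``S2`` for the separate-scalar variant.
    """
    x = np.deg2rad(np.asarray(x_deg, dtype=float))
    mu = np.deg2rad(mu_deg)
    S2 = S if S2 is None else S2
    v1 = S * np.exp(kappa1 * np.cos(x - mu)) / (2 * np.pi * special.i0(kappa1))
    v2 = S2 * np.exp(kappa2 * np.cos(x - mu)) / (2 * np.pi * special.i0(kappa2))
    return v1 - v2 + B


@dataclass
class VonMisesParams:
    S: float
    B: float
    mu: float  # degrees
    kappa1: float
    kappa2: float
    S2: float | None = None
    rss: float = np.nan
    converged: bool = True

    def __call__(self, x_deg):
        return diff_von_mises(x_deg, self.S, self.B, self.mu,
                              self.kappa1, self.kappa2, self.S2)


@dataclass
class TuningCurve:
    """Binned polar-angle tuning of attentional modulation (%BOLD)."""

    bin_centers: np.ndarray  # mean polar distance of member vertices, deg
    values: np.ndarray  # mean focal-minus-distributed modulation per bin
    counts: np.ndarray
    n_empty: int = 0


@dataclass
class SpreadEstimate:
    left: float  # x-intercept in [-60, 0], deg (NaN if missing)
    right: float  # x-intercept in [0, 60], deg
    width: float
    peak: float  # max enhancement, %BOLD
    trough: float  # min suppression, %BOLD
    absolute: float  # peak - trough
    missing_intercepts: bool = False


def rotate_points(x, y, angle_deg):
    """Rotate visual-field points counterclockwise by ``angle_deg``."""
    a = np.deg2rad(angle_deg)
    return x * np.cos(a) - y * np.sin(a), x * np.sin(a) + y * np.cos(a)


def modulation_2d_map(
    modulation,
    centers,
    rotate_to_up_from: float | None = None,
    grid_spacing: float = 0.25,
    extent: float = 12.4,
):
    """Scattered modulation samples interpolated onto a square grid.

    ``modulation`` holds one per-vertex value (focal minus distributed,
    averaged over the 49 stimuli); ``centers`` the (n, 2) average-condition
    pRF centers. With ``rotate_to_up_from`` set to the attended target's
    polar angle, points are rotated by (90 - angle) so the attended location
    lands on the upper vertical meridian. Returns (grid_axis, grid) with
    NaN outside the convex hull.
    """
    centers = np.asarray(centers, dtype=float)
    modulation = np.asarray(modulation, dtype=float)
    if centers.shape[0] < 3:
        raise ValueError("need at least 3 points to interpolate")
    x, y = centers[:, 0], centers[:, 1]
    if rotate_to_up_from is not None:
        x, y = rotate_points(x, y, 90.0 - rotate_to_up_from)
    axis = np.arange(-extent, extent + grid_spacing / 2, grid_spacing)
    gx, gy = np.meshgrid(axis, axis)
    grid = interpolate.griddata((x, y), modulation, (gx, gy), method="linear")
    return axis, grid


def polar_tuning_curve(
    modulation,
    centers,
    target_angle: float,
    bin_width: float = 20.0,
    ecc_range=(4.0, 8.0),
    glm_ve=None,
    min_glm_ve: float = 0.05,
) -> TuningCurve:
    """Bin vertex modulation by polar-angle distance from the target.

    Bins span -180..180 deg in ``bin_width`` steps (18 bins at the default);
    bin centers are the mean polar distance of member vertices. Vertices
    outside the eccentricity band, or at/below the GLM variance-explained
    threshold when ``glm_ve`` is given, are excluded. Empty bins are omitted
    and counted in ``n_empty``.
    """
    centers = np.asarray(centers, dtype=float)
    modulation = np.asarray(modulation, dtype=float)
    angle, ecc = cart_to_polar(centers[:, 0], centers[:, 1])
    keep = (ecc >= ecc_range[0]) & (ecc <= ecc_range[1])
    if glm_ve is not None:
        keep &= np.asarray(glm_ve) > min_glm_ve
    dist = np.asarray(polar_angle_distance(angle[keep], target_angle))
    vals = modulation[keep]

    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    idx = np.digitize(dist, edges) - 1
    idx = np.clip(idx, 0, edges.size - 2)
    centers_out, means, counts, n_empty = [], [], [], 0
    for b in range(edges.size - 1):
        sel = idx == b
        if not np.any(sel):
            n_empty += 1
            continue
        centers_out.append(dist[sel].mean())
        means.append(vals[sel].mean())
        counts.append(int(sel.sum()))
    return TuningCurve(
        bin_centers=np.asarray(centers_out),
        values=np.asarray(means),
        counts=np.asarray(counts),
        n_empty=n_empty,
    )


class DiffVonMisesModel(BaseEstimator):
    """Nonlinear least-squares fit of the difference-of-von-Mises profile.

    Multi-start initialization over a small (mu, kappa1, kappa2) grid with S
    seeded from the curve range and B from the curve minimum; the best start
    by RSS wins. ``shared_scale=False`` fits separate scalars for the two
    terms.
    """

    def __init__(self, shared_scale=True, mu_starts=(-20.0, 0.0, 20.0),
                 kappa1_starts=(2.0, 6.0, 12.0), kappa2_starts=(0.3, 1.0, 3.0),
                 max_nfev=2000):
        self.shared_scale = shared_scale
        self.mu_starts = mu_starts
        self.kappa1_starts = kappa1_starts
        self.kappa2_starts = kappa2_starts
        self.max_nfev = max_nfev

    def fit(self, X, y):
        """Fit to bin centers ``X`` (degrees) and bin means ``y`` (%BOLD)."""
        x = np.asarray(X, dtype=float).ravel()
        yv = np.asarray(y, dtype=float).ravel()
        if x.size < 6:
            raise ValueError("need at least 6 populated bins")
        shared = self.shared_scale

        def unpack(theta):
            if shared:
                S, B, mu, k1, k2 = theta
                return S, B, mu, k1, k2, None
            S, S2, B, mu, k1, k2 = theta
            return S, B, mu, k1, k2, S2

        def residuals(theta):
            S, B, mu, k1, k2, S2 = unpack(theta)
            return diff_von_mises(x, S, B, mu, k1, k2, S2) - yv

        s0 = max(np.ptp(yv), 1e-3)
        b0 = float(yv.min())
        best = None
        kmin = 1e-3
        for mu0 in self.mu_starts:
            for k10 in self.kappa1_starts:
                for k20 in self.kappa2_starts:
                    if shared:
                        theta0 = [s0, b0, mu0, k10, k20]
                        lb = [-np.inf, -np.inf, -180.0, kmin, kmin]
                        ub = [np.inf, np.inf, 180.0, 200.0, 200.0]
                    else:
                        theta0 = [s0, s0, b0, mu0, k10, k20]
                        lb = [-np.inf, -np.inf, -np.inf, -180.0, kmin, kmin]
                        ub = [np.inf, np.inf, np.inf, 180.0, 200.0, 200.0]
                    try:
                        res = optimize.least_squares(
                            residuals, theta0, bounds=(lb, ub),
                            max_nfev=self.max_nfev,
                        )
                    except Exception:
                        continue
                    rss = float(2 * res.cost)
                    if best is None or rss < best[0]:
                        best = (rss, res)
        if best is None:
            self.params_ = VonMisesParams(np.nan, np.nan, np.nan, np.nan,
                                          np.nan, converged=False)
            return self
        rss, res = best
        S, B, mu, k1, k2, S2 = unpack(res.x)
        self.params_ = VonMisesParams(S=float(S), B=float(B), mu=float(mu),
                                      kappa1=float(k1), kappa2=float(k2),
                                      S2=None if S2 is None else float(S2),
                                      rss=rss, converged=bool(res.success))
        return self

    def predict(self, X):
        return self.params_(np.asarray(X, dtype=float))


def fit_diff_von_mises(curve: TuningCurve, **kwargs) -> VonMisesParams:
    model = DiffVonMisesModel(**kwargs).fit(curve.bin_centers, curve.values)
    return model.params_


def attentional_spread(params: VonMisesParams, search_limit: float = 60.0,
                       grid_step: float = 0.01) -> SpreadEstimate:
    """X-intercepts, width, peak enhancement and trough suppression.

    Roots of the fitted profile are bracketed on a ``grid_step`` grid within
    [-limit, 0] and [0, limit] and polished with Brent's method; when a
    bracket contains no sign change the intercept (and the width) is flagged
    missing. Peak/trough are extrema over the enhancement and suppression
    lobes of the full -180..180 circle.
    """

    def f(x):
        return params(x)

    def find_root(lo, hi):
        xs = np.arange(lo, hi + grid_step / 2, grid_step)
        ys = f(xs)
        sign_change = np.nonzero(np.diff(np.signbit(ys)))[0]
        if sign_change.size == 0:
            return np.nan
        j = sign_change[0] if lo < 0 else sign_change[-1]
        return float(optimize.brentq(f, xs[j], xs[j + 1]))

    left = find_root(-search_limit, 0.0)
    right = find_root(0.0, search_limit)
    missing = np.isnan(left) or np.isnan(right)
    width = np.nan if missing else right - left

    xs = np.arange(-180.0, 180.0 + 0.05, 0.1)
    ys = f(xs)
    peak = float(ys.max())
    trough = float(ys.min())
    return SpreadEstimate(
        left=left, right=right, width=width,
        peak=peak, trough=trough, absolute=peak - trough,
        missing_intercepts=bool(missing),
    )
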