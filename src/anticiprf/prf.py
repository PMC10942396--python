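"""Isotropic 2D-Gaussian pRF model fit to 49-stimulus beta profiles.

The model predicts the response to each mapping stimulus as the pointwise
product of a unit-peak circular Gaussian with the binary aperture, summed
over pixels and normalized by the Gaussian's pixel sum, scaled by a gain.
Fitting is coarse-to-fine: an exhaustive (x, y, sigma) grid with the gain
solved in closed form at each point, then bounded derivative-free refinement
from the best grid point. R^2 = 1 - RSS/TSS with TSS the (uncentered) sum of
squares of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .design import CONDITIONS, N_STIMULI, ApertureSet

__all__ = [
    "PRFParams",
    "FitConfig",
    "GaussianPRFModel",
    "predict_beta_profile",
    "fit_prf",
    "fit_prfs_by_condition",
    "fit_population_by_condition",
    "fit_size_eccentricity",
]


@dataclass
class PRFParams:
    """One pRF solution: center (deg), size (one SD, deg), gain, R^2."""

    x: float
    y: float
    sigma: float
    gain: float
    r2: float
    condition: str | None = None
    degenerate: bool = False

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x, self.y))


@dataclass
class FitConfig:
    """Coarse-grid and refinement settings.

    The coarse stage scans centers on a ``grid_step``-spaced lattice within
    the stimulus window and ``n_sigma`` log-spaced sizes over ``sigma_range``;
    refinement is bounded with centers within +/- ``center_bound`` and sigma
    in ``sigma_bounds``.
    """

    grid_step: float = 1.0
    sigma_range: tuple = (0.25, 8.0)
    n_sigma: int = 10
    center_bound: float = 14.0
    sigma_bounds: tuple = (0.1, 12.0)
    include_blank: bool = True
    xtol: float = 1e-4

    def sigma_levels(self) -> np.ndarray:
        return np.geomspace(self.sigma_range[0], self.sigma_range[1], self.n_sigma)


def _gaussian_overlaps(apertures: ApertureSet, xs, ys, sigmas) -> np.ndarray:
    """Unit-gain predictions for aligned (x, y, sigma) arrays.

    Returns (n_points, n_apertures); each row is the normalized overlap of a
    unit-peak Gaussian with every aperture.
    """
    A = apertures.flat()  # (49, P)
    X, Y = apertures.pixel_coords()
    px, py = X.ravel(), Y.ravel()
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    out = np.empty((xs.size, A.shape[0]))
    chunk = max(1, int(4e6 // px.size))
    for lo in range(0, xs.size, chunk):
        hi = min(lo + chunk, xs.size)
        d2 = (px[None, :] - xs[lo:hi, None]) ** 2 + (py[None, :] - ys[lo:hi, None]) ** 2
        G = np.exp(-d2 / (2.0 * sigmas[lo:hi, None] ** 2))
        out[lo:hi] = (G @ A.T) / G.sum(axis=1, keepdims=True)
    return out


def predict_beta_profile(params: PRFParams, apertures: ApertureSet) -> np.ndarray:
    """Predicted response to each mapping stimulus (blank predicts 0)."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    return params.gain * _gaussian_overlaps(
        apertures, params.x, params.y, params.sigma
    )[0]


def _grid_cache(apertures: ApertureSet, config: FitConfig):
    """Per-aperture-set memo of coarse-grid points and their predictions."""
    key = (config.grid_step, config.sigma_range, config.n_sigma)
    cache = getattr(apertures, "_prf_grid_cache", None)
    if cache is not None and cache[0] == key:
        return cache[1]
    e = apertures.grid_extent
    axis = np.arange(-np.floor(e / config.grid_step), np.floor(e / config.grid_step) + 1)
    axis = axis * config.grid_step
    gx, gy = np.meshgrid(axis, axis)
    keep = gx**2 + gy**2 <= e**2
    gx, gy = gx[keep], gy[keep]
    sig = config.sigma_levels()
    xs = np.repeat(gx, sig.size)
    ys = np.repeat(gy, sig.size)
    ss = np.tile(sig, gx.size)
    P = _gaussian_overlaps(apertures, xs, ys, ss)
    data = (np.column_stack([xs, ys, ss]), P)
    apertures._prf_grid_cache = (key, data)
    return data


class GaussianPRFModel(BaseEstimator):
    """Coarse-to-fine estimator of isotropic Gaussian pRFs.

    Parameters
    ----------
    apertures : ApertureSet
        The 49 mapping-stimulus masks the predictions are computed from.
    config : FitConfig, optional
        Grid and refinement settings.
    refine : bool
        If False, return the best coarse-grid solution.

    Attributes (after ``fit``)
    --------------------------
    x_, y_, sigma_, gain_, r2_, rss_ : (n_profiles,) arrays
    degenerate_ : boolean mask of all-zero input profiles (parameters NaN).
    """

    def __init__(self, apertures=None, config=None, refine=True):
        self.apertures = apertures
        self.config = config
        self.refine = refine

    def _stim_mask(self, cfg) -> np.ndarray:
        mask = np.ones(self.apertures.n_apertures, dtype=bool)
        if not cfg.include_blank:
            mask[-1] = False
        return mask

    def fit(self, X, y=None):
        """Fit one pRF per row of X ((n_profiles, 49) or a single profile)."""
        if self.apertures is None:
            raise ValueError("apertures must be provided")
        cfg = self.config or FitConfig()
        B = np.atleast_2d(np.asarray(X, dtype=float))
        if B.shape[1] != self.apertures.n_apertures:
            raise ValueError("profiles must have one beta per aperture")
        if not np.all(np.isfinite(B)):
            raise ValueError("beta profiles must be finite")
        mask = self._stim_mask(cfg)
        grid, P = _grid_cache(self.apertures, cfg)
        Pm = P[:, mask]
        pp = np.sum(Pm**2, axis=1)

        n = B.shape[0]
        out = np.full((n, 6), np.nan)  # x, y, sigma, gain, r2, rss
        degenerate = np.zeros(n, dtype=bool)
        for i in range(n):
            b = B[i, mask]
            tss = float(b @ b)
            if tss == 0.0:
                degenerate[i] = True
                continue
            pb = Pm @ b
            gains = pb / pp
            rss_grid = tss - gains * pb
            j = int(np.argmin(rss_grid))
            x0 = grid[j]
            best = (x0, float(rss_grid[j]), float(gains[j]))
            if self.refine:
                best = self._refine(b, x0, best, cfg, mask)
            (xys, rss, gain) = best
            out[i] = (*xys, gain, 1.0 - rss / tss, rss)
        self.x_, self.y_, self.sigma_ = out[:, 0], out[:, 1], out[:, 2]
        self.gain_, self.r2_, self.rss_ = out[:, 3], out[:, 4], out[:, 5]
        self.degenerate_ = degenerate
        self.n_profiles_ = n
        return self

    def _refine(self, b, x0, grid_best, cfg, mask):
        apertures = self.apertures
        tssb = float(b @ b)

        def objective(theta):
            x, y, s = theta
            p = _gaussian_overlaps(apertures, x, y, s)[0][mask]
            pp = float(p @ p)
            if pp == 0.0:
                return tssb
            pb = float(p @ b)
            return tssb - pb * pb / pp

        bounds = [
            (-cfg.center_bound, cfg.center_bound),
            (-cfg.center_bound, cfg.center_bound),
            cfg.sigma_bounds,
        ]
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            bounds=bounds, options={"xatol": cfg.xtol, "fatol": 1e-12},
        )
        if res.fun <= grid_best[1]:
            x, y, s = res.x
            p = _gaussian_overlaps(apertures, x, y, s)[0][mask]
            gain = float(p @ b) / float(p @ p)
            return (res.x, float(res.fun), gain)
        return grid_best

    def params_(self, i: int = 0, condition: str | None = None) -> PRFParams:
        """Fitted parameters of profile ``i`` as a PRFParams record."""
        return PRFParams(
            x=float(self.x_[i]), y=float(self.y_[i]), sigma=float(self.sigma_[i]),
            gain=float(self.gain_[i]), r2=float(self.r2_[i]), condition=condition,
            degenerate=bool(self.degenerate_[i]),
        )

    def predict(self, X=None) -> np.ndarray:
        """Fitted beta-profile predictions, one row per fitted profile."""
        preds = np.full((self.n_profiles_, self.apertures.n_apertures), np.nan)
        ok = ~self.degenerate_
        if np.any(ok):
            P = _gaussian_overlaps(
                self.apertures, self.x_[ok], self.y_[ok], self.sigma_[ok]
            )
            preds[ok] = self.gain_[ok, None] * P
        return preds


def fit_prf(betas, apertures, config: FitConfig | None = None) -> PRFParams:
    """Fit a single 49-beta profile; all-zero input yields a degenerate flag."""
    model = GaussianPRFModel(apertures=apertures, config=config).fit(betas)
    return model.params_(0)


def fit_prfs_by_condition(
    condition_betas, apertures, config: FitConfig | None = None
) -> dict:
    """Six independent fits: one per attention condition plus their average."""
    B = np.asarray(condition_betas, dtype=float)
    if B.shape != (5, N_STIMULI):
        raise ValueError("expected a (5, 49) array of per-condition betas")
    profiles = np.vstack([B, B.mean(axis=0)])
    labels = list(CONDITIONS) + ["average"]
    model = GaussianPRFModel(apertures=apertures, config=config).fit(profiles)
    return {lab: model.params_(i, condition=lab) for i, lab in enumerate(labels)}


def fit_population_by_condition(
    betas, apertures, config: FitConfig | None = None, map_labels=None
) -> pd.DataFrame:
    """Per-vertex, per-condition (+average) pRF fits as a tidy table.

    ``betas`` is (n_vertices, 5, 49). Returns one row per vertex x condition
    with columns vertex, map, condition, x, y, sigma, gain, r2.
    """
    B = np.asarray(betas, dtype=float)
    n_v = B.shape[0]
    profiles = np.concatenate([B, B.mean(axis=1, keepdims=True)], axis=1)
    flat = profiles.reshape(n_v * 6, N_STIMULI)
    model = GaussianPRFModel(apertures=apertures, config=config).fit(flat)
    labels = list(CONDITIONS) + ["average"]
    rows = pd.DataFrame(
        {
            "vertex": np.repeat(np.arange(n_v), 6),
            "condition": np.tile(labels, n_v),
            "x": model.x_, "y": model.y_, "sigma": model.sigma_,
            "gain": model.gain_, "r2": model.r2_,
            "degenerate": model.degenerate_,
        }
    )
    if map_labels is not None:
        rows.insert(1, "map", np.repeat(np.asarray(map_labels), 6))
    rows["eccentricity"] = np.hypot(rows["x"], rows["y"])
    return rows


def fit_size_eccentricity(prfs: pd.DataFrame) -> pd.DataFrame:
    """Per-map OLS of pRF size on eccentricity.

    ``prfs`` needs columns map, sigma and eccentricity (or x, y). Maps with
    fewer than two distinct eccentricities are flagged degenerate.
    """
    df = prfs.copy()
    if "eccentricity" not in df:
        df["eccentricity"] = np.hypot(df["x"], df["y"])
    records = []
    for map_label, grp in df.groupby("map", sort=False):
        ecc = grp["eccentricity"].to_numpy()
        sig = grp["sigma"].to_numpy()
        ok = np.isfinite(ecc) & np.isfinite(sig)
        if np.unique(ecc[ok]).size < 2:
            records.append({"map": map_label, "intercept": np.nan,
                            "slope": np.nan, "degenerate": True})
            continue
        slope, intercept = np.polyfit(ecc[ok], sig[ok], 1)
        records.append({"map": map_label, "intercept": float(intercept),
                        "slope": float(slope), "degenerate": False})
    return pd.DataFrame(records)
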