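"""Harmonic regression with 24 h and 12 h components.

The model is

    X(t) = a*sin(2*pi*t/24) + b*cos(2*pi*t/24)
         + d*sin(2*pi*t/12) + e*cos(2*pi*t/12) + f

with t in hours and X in log2 units.  The coefficient of determination R^2 of
this fit is the rhythmicity score used throughout the package; peak and
trough times are located on a dense grid over one cycle because the second
harmonic makes the argmax non-analytic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

#: grid step (hours) for locating the fitted peak/trough within [0, 24)
PEAK_GRID_H = 0.01

_MIN_SAMPLES = 6  # 5 parameters + 1


def _design(t: np.ndarray) -> np.ndarray:
    w1 = 2.0 * np.pi * t / 24.0
    w2 = 2.0 * np.pi * t / 12.0
    return np.column_stack([np.sin(w1), np.cos(w1), np.sin(w2), np.cos(w2), np.ones_like(t)])


@dataclass(frozen=True)
class HarmonicFit:
    """Fitted harmonic model for one gene.

    ``amplitude`` is half the fitted peak-to-trough range; ``mesor`` is the
    intercept f (the rhythm-adjusted mean).  ``degenerate`` marks
    zero-variance input, for which R^2 is defined as 0.
    """

    a: float
    b: float
    d: float
    e: float
    f: float
    r2: float
    peak_h: float
    trough_h: float
    amplitude: float
    mesor: float
    degenerate: bool = False

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.a, self.b, self.d, self.e, self.f])

    def predict(self, t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return _design(t) @ self.coef


class HarmonicRegression(RegressorMixin, BaseEstimator):
    """Least-squares 24 h + 12 h harmonic regression, sklearn style.

    Parameters
    ----------
    peak_grid_h : float, default 0.01
        Resolution (hours) of the grid used to locate peak and trough of the
        fitted curve over one 24 h cycle.

    Attributes
    ----------
    coef_ : ndarray of shape (4,)
        (a, b, d, e) — sine/cosine coefficients of the two harmonics.
    intercept_ : float
        f, the mesor.
    r2_ : float
        Coefficient of determination against the sample mean; 0 (with
        ``degenerate_`` set) for zero-variance input.
    peak_h_, trough_h_ : float
        Argmax/argmin of the fitted curve in [0, 24).
    amplitude_ : float
        Half the fitted peak-to-trough range, log2 units.
    """

    def __init__(self, peak_grid_h: float = PEAK_GRID_H):
        self.peak_grid_h = peak_grid_h

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape[0] != y.shape[0]:
            raise ValueError("times and values must have equal length")
        if t.shape[0] < _MIN_SAMPLES:
            raise ValueError(
                f"harmonic fit needs >= {_MIN_SAMPLES} samples (5 parameters), got {t.shape[0]}"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("times and values must be finite")

        A = _design(t)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.degenerate_ = ss_tot == 0.0
        if self.degenerate_:
            coef = np.array([0.0, 0.0, 0.0, 0.0, float(y.mean())])
            self.r2_ = 0.0
        else:
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            ss_res = float(np.sum((y - A @ coef) ** 2))
            self.r2_ = 1.0 - ss_res / ss_tot
        self.coef_ = coef[:4]
        self.intercept_ = float(coef[4])

        grid = np.arange(0.0, 24.0, self.peak_grid_h)
        curve = _design(grid) @ coef
        self.peak_h_ = float(grid[np.argmax(curve)])
        self.trough_h_ = float(grid[np.argmin(curve)])
        self.amplitude_ = float((curve.max() - curve.min()) / 2.0)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return _design(t) @ np.append(self.coef_, self.intercept_)

    def to_fit(self) -> HarmonicFit:
        a, b, d, e = (float(c) for c in self.coef_)
        return HarmonicFit(
            a=a, b=b, d=d, e=e, f=self.intercept_,
            r2=float(self.r2_), peak_h=self.peak_h_, trough_h=self.trough_h_,
            amplitude=self.amplitude_, mesor=self.intercept_,
            degenerate=bool(self.degenerate_),
        )


def fit_harmonic(values, times_h) -> HarmonicFit:
    """Fit the harmonic model to one gene's per-sample log2 levels.

    Times are used as given (unwrapped); the model is 24 h-periodic, so
    multi-day series need no wrapping.  Zero-variance input yields a
    degenerate fit with R^2 = 0 rather than an error.
    """
    return HarmonicRegression().fit(times_h, values).to_fit()


def wrap_phase_diff(delta_h: float) -> float:
    """Wrap an hour difference into (-12, 12]."""
    w = float(np.mod(delta_h, 24.0))
    return w - 24.0 if w > 12.0 else w


def phase_difference(fit_g: HarmonicFit, fit_ref: HarmonicFit) -> float:
    """Peak-to-peak phase difference, gene minus reference, in (-12, 12].

    Negative values mean the gene peaks before the reference.
    """
    if fit_g.degenerate or fit_ref.degenerate:
        raise ValueError("phase difference undefined for degenerate fits")
    return wrap_phase_diff(fit_g.peak_h - fit_ref.peak_h)


def fit_all(matrix) -> pd.DataFrame:
    """Fit the harmonic model to every gene of a time-annotated matrix.

    Returns a per-gene table with columns a, b, d, e, f, r2, peak_h,
    trough_h, amplitude, mesor, degenerate.  Degenerate (zero-variance)
    genes are flagged, not dropped.
    """
    if matrix.sample_times_h is None or matrix.sample_times_h.isna().all():
        raise ValueError(
            "matrix has no sample time annotation; for snapshot data assign "
            "phases first (see the phasing module)"
        )
    times = matrix.sample_times_h.reindex(matrix.samples)
    usable = times.notna()
    if usable.sum() < _MIN_SAMPLES:
        raise ValueError(
            f"harmonic fit needs >= {_MIN_SAMPLES} time-annotated samples, got {int(usable.sum())}"
        )
    t = times[usable].to_numpy(dtype=float)
    cols = [s for s, ok in zip(matrix.samples, usable) if ok]

    # one shared least-squares solve for all non-degenerate genes
    A = _design(t)
    Y = matrix.values.loc[:, cols].to_numpy(dtype=float).T  # samples x genes
    coefs, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ coefs
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    degenerate = ss_tot == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(degenerate, 0.0, 1.0 - ss_res / np.where(degenerate, 1.0, ss_tot))
    coefs[:4, degenerate] = 0.0
    coefs[4, degenerate] = Y.mean(axis=0)[degenerate]

    grid = np.arange(0.0, 24.0, PEAK_GRID_H)
    curves = _design(grid) @ coefs  # grid x genes
    peak_h = grid[np.argmax(curves, axis=0)]
    trough_h = grid[np.argmin(curves, axis=0)]
    amplitude = (curves.max(axis=0) - curves.min(axis=0)) / 2.0

    return pd.DataFrame(
        {
            "a": coefs[0], "b": coefs[1], "d": coefs[2], "e": coefs[3], "f": coefs[4],
            "r2": r2, "peak_h": peak_h, "trough_h": trough_h,
            "amplitude": amplitude, "mesor": coefs[4], "degenerate": degenerate,
        },
        index=pd.Index(matrix.genes, name="gene"),
    )
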