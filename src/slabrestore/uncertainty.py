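"""Evidential uncertainty maps and uncertainty-to-quality calibration.

The network's evidential head parameterises a Normal-Inverse-Gamma
posterior p(mu, sigma^2 | gamma, v, alpha, beta) per voxel, from which

    prediction  E[mu]       = gamma,
    aleatoric   E[sigma^2]  = beta / (alpha - 1),
    epistemic   Var[mu]     = beta / (v (alpha - 1)),

so ``epistemic * v == aleatoric`` identically.  Slice-mean epistemic
uncertainty correlates strongly with slice SSIM (linear trend) and PSNR
(exponential trend, PSNR being logarithmic); fitting those regressions
on data with known ground truth yields a calibration that predicts the
quality of new reconstructions, with 95% prediction intervals, when no
ground truth is available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .volume import plane_axis

__all__ = [
    "EvidentialMaps",
    "UncertaintyMaps",
    "moments",
    "slice_mean_epistemic",
    "QualityCalibrator",
    "fit_calibration",
    "predict_quality",
]


@dataclass(frozen=True)
class EvidentialMaps:
    """Per-voxel NIG hyperparameters (gamma, v, alpha, beta)."""

    gamma: np.ndarray
    v: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        shapes = {np.shape(m) for m in (self.gamma, self.v, self.alpha, self.beta)}
        if len(shapes) != 1:
            raise ValueError("evidential maps must share one shape")
        if np.any(np.asarray(self.v) <= 0) or np.any(np.asarray(self.beta) <= 0):
            raise ValueError("require v > 0 and beta > 0 everywhere")
        if np.any(np.asarray(self.alpha) <= 1):
            raise ValueError("require alpha > 1 everywhere (moments undefined otherwise)")


@dataclass(frozen=True)
class UncertaintyMaps:
    aleatoric: np.ndarray
    epistemic: np.ndarray


def moments(maps: EvidentialMaps):
    """Prediction and (aleatoric, epistemic) maps from NIG hyperparameters."""
    alpha = np.asarray(maps.alpha, dtype=np.float64)
    beta = np.asarray(maps.beta, dtype=np.float64)
    v = np.asarray(maps.v, dtype=np.float64)
    aleatoric = beta / (alpha - 1.0)
    epistemic = aleatoric / v
    return np.asarray(maps.gamma, dtype=np.float64), UncertaintyMaps(aleatoric, epistemic)


def slice_mean_epistemic(u: UncertaintyMaps, plane: str = "sagittal") -> np.ndarray:
    """Mean epistemic uncertainty over the in-plane voxels of each slice."""
    epi = np.asarray(u.epistemic, dtype=np.float64)
    if epi.size == 0:
        raise ValueError("empty uncertainty volume")
    axis = plane_axis(plane)
    inplane = tuple(a for a in range(epi.ndim) if a != axis)
    return epi.mean(axis=inplane)


def _exp3(u, c, d, e):
    return c * np.exp(d * u) + e


def _exp2(u, c, d):
    return c * np.exp(d * u)


class QualityCalibrator(BaseEstimator, RegressorMixin):
    """Regression from slice-mean epistemic uncertainty to an image metric.

    Parameters
    ----------
    kind : {"linear_ssim", "exp_psnr"}
        ``linear_ssim`` fits ``metric = a*u + b`` by ordinary least
        squares; ``exp_psnr`` fits ``metric = c*exp(d*u) + e`` by
        nonlinear least squares with log-linear initialisation (a
        2-parameter ``c*exp(d*u)`` variant is available via
        ``offset=False``).
    level : float
        Prediction-interval coverage (default 0.95).

    Fitted attributes: ``coef_`` (the model coefficients), ``r2_``,
    ``sigma_`` (residual scale), ``dof_``, ``u_range_``.
    Prediction intervals use the classical frequentist formula in the
    linear case and a delta-method approximation for the exponential
    fit.
    """

    def __init__(self, kind: str = "linear_ssim", level: float = 0.95, offset: bool = True):
        self.kind = kind
        self.level = level
        self.offset = offset

    # -- fitting -------------------------------------------------------------
    def fit(self, u, y):
        u = np.asarray(u, dtype=np.float64).ravel()
        y = np.asarray(y, dtype=np.float64).ravel()
        if u.size != y.size:
            raise ValueError("u and y must have equal length")
        if u.size < 10:
            raise ValueError("need at least 10 paired observations")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite observations")
        if np.var(u) <= 1e-14 * max(1.0, float(np.mean(u)) ** 2):
            raise ValueError("degenerate predictor: zero variance")
        if self.kind == "linear_ssim":
            self._fit_linear(u, y)
        elif self.kind == "exp_psnr":
            self._fit_exp(u, y)
        else:
            raise ValueError(f"unknown calibration kind {self.kind!r}")
        self.u_range_ = (float(u.min()), float(u.max()))
        self.n_ = int(u.size)
        ss_res = float(np.sum((y - self._point(u)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return self

    def _fit_linear(self, u, y):
        import statsmodels.api as sm

        res = sm.OLS(y, sm.add_constant(u)).fit()
        b, a = res.params  # intercept, slope
        self.coef_ = {"a": float(a), "b": float(b)}
        self.dof_ = int(res.df_resid)
        self.sigma_ = float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0
        self._ubar = float(u.mean())
        self._sxx = float(np.sum((u - u.mean()) ** 2))

    def _fit_exp(self, u, y):
        # log-linear initialisation: peel off an offset near the smallest y
        span = float(y.max() - y.min())
        e0 = float(y.min() - 0.05 * span - 1e-9) if self.offset else 0.0
        z = np.log(np.maximum(y - e0, 1e-12))
        d0, logc0 = np.polyfit(u, z, 1)
        p0 = [np.exp(logc0), d0, e0] if self.offset else [np.exp(logc0), d0]
        fn = _exp3 if self.offset else _exp2
        popt, pcov = optimize.curve_fit(fn, u, y, p0=p0, maxfev=20000)
        names = ("c", "d", "e") if self.offset else ("c", "d")
        self.coef_ = {k: float(v) for k, v in zip(names, popt)}
        self._pcov = np.asarray(pcov, dtype=np.float64)
        self.dof_ = int(u.size - len(popt))
        resid = y - fn(u, *popt)
        self.sigma_ = float(np.sqrt(np.sum(resid ** 2) / self.dof_)) if self.dof_ > 0 else 0.0

    # -- prediction ---------------------------------------------------------
    def _point(self, u):
        c = self.coef_
        if self.kind == "linear_ssim":
            return c["a"] * u + c["b"]
        if self.offset:
            return _exp3(u, c["c"], c["d"], c["e"])
        return _exp2(u, c["c"], c["d"])

    def _half_width(self, u):
        tcrit = stats.t.ppf(0.5 + self.level / 2.0, self.dof_) if self.dof_ > 0 else 0.0
        if self.kind == "linear_ssim":
            se = self.sigma_ * np.sqrt(1.0 + 1.0 / self.n_ + (u - self._ubar) ** 2 / self._sxx)
            return tcrit * se
        c, d = self.coef_["c"], self.coef_["d"]
        grads = [np.exp(d * u), c * u * np.exp(d * u)]
        if self.offset:
            grads.append(np.ones_like(u))
        G = np.stack(grads, axis=-1)
        var_fit = np.einsum("...i,ij,...j->...", G, self._pcov, G)
        return tcrit * np.sqrt(np.maximum(var_fit, 0.0) + self.sigma_ ** 2)

    def predict(self, u, return_interval: bool = False):
        """Point prediction (and optional 95% prediction interval) at ``u``."""
        check_is_fitted(self, "coef_")
        u = np.asarray(u, dtype=np.float64)
        lo, hi = self.u_range_
        width = hi - lo
        if np.any(u < lo - width) or np.any(u > hi + width):
            warnings.warn(
                "predictor outside twice the fitted range; extrapolated quality "
                "estimates are unreliable", UserWarning, stacklevel=2,
            )
        point = self._point(u)
        if not return_interval:
            return point
        half = self._half_width(u)
        return point, (point - half, point + half)

    # -- serialization --------------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        payload = {
            "kind": self.kind, "level": self.level, "offset": self.offset,
            "coefficients": self.coef_, "sigma": self.sigma_, "dof": self.dof_,
            "r2": self.r2_, "n": self.n_, "u_range": list(self.u_range_),
        }
        if self.kind == "linear_ssim":
            payload["ubar"] = self._ubar
            payload["sxx"] = self._sxx
        else:
            payload["pcov"] = self._pcov.tolist()
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "QualityCalibrator":
        d = json.loads(text)
        model = cls(kind=d["kind"], level=d["level"], offset=d["offset"])
        model.coef_ = d["coefficients"]
        model.sigma_ = d["sigma"]
        model.dof_ = d["dof"]
        model.r2_ = d["r2"]
        model.n_ = d["n"]
        model.u_range_ = tuple(d["u_range"])
        if d["kind"] == "linear_ssim":
            model._ubar = d["ubar"]
            model._sxx = d["sxx"]
        else:
            model._pcov = np.asarray(d["pcov"])
        return model


def fit_calibration(u_means, metric_values, kind: str = "linear_ssim") -> QualityCalibrator:
    """Fit a :class:`QualityCalibrator` on paired (uncertainty, metric) data."""
    return QualityCalibrator(kind=kind).fit(u_means, metric_values)


def predict_quality(model: QualityCalibrator, u_mean):
    """Point estimate and 95% prediction interval of the metric at ``u_mean``."""
    return model.predict(u_mean, return_interval=True)
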