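"""Almon polynomial distributed-lag sub-model.

Monthly temperature enters the sex-ratio model at the 19 lags −9..+9 around
the conception month.  Estimating 19 free lag coefficients directly is
ill-posed (the lag columns are strongly inter-correlated), so the classical
econometric regularization is used: the lag-coefficient sequence is
constrained to a polynomial of low degree ``d`` in the lag index,

    beta_l = sum_j theta_j q_j(l),   l = lag_min..lag_max,

with ``q_j`` an orthonormalized polynomial basis.  The reduced design
``(lag matrix) @ T`` contributes only ``d+1`` parametric columns to the GAM;
the fitted polynomial coefficients and their covariance are mapped back to the
per-lag scale (delta method) to give the lag-coefficient table with pointwise
95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gam import GamFit

__all__ = ["AlmonSpec", "almon_transform", "fold_lag_term", "recover_lag_coefficients"]

LAG_MIN = -9
LAG_MAX = 9


@dataclass(frozen=True)
class AlmonSpec:
    """Lag window and polynomial degree of the distributed-lag constraint."""

    lag_min: int = LAG_MIN
    lag_max: int = LAG_MAX
    degree: int = 3

    def __post_init__(self) -> None:
        if self.lag_max < self.lag_min:
            raise ValueError("lag_max < lag_min")
        if not 0 <= self.degree <= self.n_lags - 1:
            raise ValueError(f"degree must be in 0..{self.n_lags - 1}, got {self.degree}")

    @property
    def n_lags(self) -> int:
        return self.lag_max - self.lag_min + 1

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.lag_min, self.lag_max + 1)


def almon_transform(spec: AlmonSpec) -> np.ndarray:
    """Transform matrix ``T`` (L x (d+1)) with ``beta = T @ theta``.

    Columns span the polynomials of degree 0..d in the (re-centred) lag index
    and are orthonormalized by QR for conditioning; signs are fixed so the
    matrix is deterministic.
    """
    L, d = spec.n_lags, spec.degree
    idx = np.arange(L, dtype=float)
    idx = (idx - idx.mean()) / max(idx.std(), 1.0)  # centring/scaling for conditioning
    V = np.vander(idx, d + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    return Q * sign


def fold_lag_term(frame: pd.DataFrame, spec: AlmonSpec) -> np.ndarray:
    """Reduced design columns ``(n x (d+1))``: lag-temperature matrix times T.

    ``frame`` must carry complete lag columns ``temp_lag[m]`` for every lag in
    the window (the model-frame assembly drops incomplete rows upstream).
    """
    cols = [f"temp_lag[{l}]" for l in spec.lags]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"model frame lacks lag columns: {missing}")
    Lmat = frame[cols].to_numpy(dtype=float)
    if np.isnan(Lmat).any():
        bad = frame.index[np.isnan(Lmat).any(axis=1)][:5].tolist()
        raise ValueError(f"missing lag temperatures in rows {bad}; filter upstream")
    return Lmat @ almon_transform(spec)


def recover_lag_coefficients(
    fit: GamFit,
    spec: AlmonSpec,
    term: str = "almon",
    level: float = 0.95,
) -> pd.DataFrame:
    """Back-transform the folded polynomial block to per-lag coefficients.

    Returns a table with one row per lag: ``coef`` (logit per °C), ``se``,
    pointwise confidence limits ``L``/``U`` and a ``significant`` flag
    (interval excluding zero).
    """
    T = almon_transform(spec)
    theta = fit.coef_block(term)
    Vtheta = fit.cov_block(term)
    if theta.size != spec.degree + 1:
        raise ValueError(
            f"folded block '{term}' has {theta.size} coefficients, expected {spec.degree + 1}"
        )
    beta = T @ theta
    Vbeta = T @ Vtheta @ T.T
    se = np.sqrt(np.maximum(np.diag(Vbeta), 0.0))
    zq = norm.ppf(0.5 + level / 2.0)
    lo, hi = beta - zq * se, beta + zq * se
    return pd.DataFrame(
        {
            "lag": spec.lags,
            "coef": beta,
            "se": se,
            "L": lo,
            "U": hi,
            "significant": (lo > 0) | (hi < 0),
        }
    )
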