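"""Single-kernel REML variance components and genomic BLUP prediction.

The model is the univariate animal model

    y = 1 mu + a + e,   a ~ N(0, sigma2_a K),   e ~ N(0, sigma2_e I)

on pre-adjusted phenotypes, so the only fixed effect is the intercept.
REML is solved exactly by the spectral trick: the kernel is
eigendecomposed once, which diagonalises the covariance for every value of
the variance ratio lambda = sigma2_a / sigma2_e, and the profiled
restricted log-likelihood is maximised by Brent search over log(lambda).

The kernel is rescaled internally to mean diagonal 1 before estimation
(the conventional genomic-relationship normalisation), so sigma2_a is
expressed per unit of average genomic relationship and the reported h2 is
invariant to the arbitrary scaling constants of the different kernels.
Predictions are unaffected by this choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .kernels import Kernel

RIDGE = 1e-6          # added to the kernel diagonal at solve time only
H2_BOUNDS = (1e-4, 1 - 1e-4)
BRENT_XTOL = 1e-10


@dataclass
class VarianceComponents:
    sigma2_a: float       # additive variance on the mean-diag-1 kernel scale
    sigma2_e: float
    h2: float             # sigma2_a / (sigma2_a + sigma2_e)
    se_h2: float
    loglik: float         # restricted log-likelihood (up to an additive constant)
    converged: bool
    boundary: bool = False  # h2 pinned at its search bound


@dataclass
class DGVSet:
    individuals: list[str]
    dgv: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"individual": self.individuals, "dgv": self.dgv})


def _normalized(K: np.ndarray) -> tuple[np.ndarray, float]:
    scale = float(np.mean(np.diag(K)))
    if scale <= 0:
        raise ValueError("kernel has non-positive mean diagonal")
    return K / scale, scale


def _check_psd(K: np.ndarray) -> np.ndarray:
    """Eigenvalues of the ridged kernel; error if indefinite beyond tolerance."""
    w = eigh(K, eigvals_only=True, check_finite=False)
    if w[0] < -1e-8:
        raise ValueError(
            f"kernel is not positive semidefinite (min eigenvalue {w[0]:.3e})"
        )
    return w


def _profile_restricted_loglik(lam: float, d: np.ndarray, yt: np.ndarray,
                               xt: np.ndarray) -> tuple[float, float, float]:
    """Profiled restricted log-likelihood at variance ratio lambda.

    Returns (loglik, sigma2_e_hat, mu_hat) with sigma2_a = lambda*sigma2_e.
    """
    n = len(d)
    v = lam * d + 1.0           # eigenvalues of H = lam*K + I
    xx = np.sum(xt * xt / v)
    xy = np.sum(xt * yt / v)
    mu = xy / xx
    r = yt - mu * xt
    q = float(np.sum(r * r / v))
    s2e = q / (n - 1)
    ll = -0.5 * ((n - 1) * (np.log(s2e) + 1.0) + np.sum(np.log(v)) + np.log(xx))
    return float(ll), s2e, float(mu)


def reml_single_kernel(y: np.ndarray, k: Kernel,
                       ridge: float = RIDGE) -> VarianceComponents:
    """REML estimates of (sigma2_a, sigma2_e, h2) for one kernel.

    A boundary estimate (h2 at the edge of its search interval) is flagged,
    not fatal.  The standard error of h2 comes from the inverse observed
    information of the restricted likelihood in (sigma2_a, sigma2_e),
    propagated by the delta method.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two phenotyped individuals")
    Kn, _ = _normalized(k.matrix)
    _check_psd(Kn)
    Kr = Kn + ridge * np.eye(n)
    d, U = eigh(Kr, check_finite=False)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    lo = np.log(H2_BOUNDS[0] / (1 - H2_BOUNDS[0]))
    hi = np.log(H2_BOUNDS[1] / (1 - H2_BOUNDS[1]))
    res = minimize_scalar(
        lambda loglam: -_profile_restricted_loglik(np.exp(loglam), d, yt, xt)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": BRENT_XTOL},
    )
    lam = float(np.exp(res.x))
    ll, s2e, _ = _profile_restricted_loglik(lam, d, yt, xt)
    s2a = lam * s2e
    h2 = s2a / (s2a + s2e)
    boundary = h2 <= H2_BOUNDS[0] * 1.01 or h2 >= H2_BOUNDS[1] / 1.01

    se_h2 = _se_h2(s2a, s2e, d, yt, xt)
    return VarianceComponents(
        sigma2_a=s2a, sigma2_e=s2e, h2=h2, se_h2=se_h2,
        loglik=ll, converged=bool(res.success), boundary=bool(boundary),
    )


def _restricted_loglik_full(s2a: float, s2e: float, d: np.ndarray,
                            yt: np.ndarray, xt: np.ndarray) -> float:
    """Unprofiled restricted log-likelihood at (sigma2_a, sigma2_e)."""
    v = s2a * d + s2e
    xx = np.sum(xt * xt / v)
    xy = np.sum(xt * yt / v)
    mu = xy / xx
    r = yt - mu * xt
    return float(-0.5 * (np.sum(np.log(v)) + np.log(xx) + np.sum(r * r / v)))


def _se_h2(s2a: float, s2e: float, d: np.ndarray, yt: np.ndarray,
           xt: np.ndarray) -> float:
    """Delta-method SE of h2 from the numerical observed information."""
    theta = np.array([s2a, s2e])
    step = np.maximum(1e-5 * np.abs(theta), 1e-10)
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * step[i]
            ej = np.eye(2)[j] * step[j]
            fpp = _restricted_loglik_full(*(theta + ei + ej), d, yt, xt)
            fpm = _restricted_loglik_full(*(theta + ei - ej), d, yt, xt)
            fmp = _restricted_loglik_full(*(theta - ei + ej), d, yt, xt)
            fmm = _restricted_loglik_full(*(theta - ei - ej), d, yt, xt)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step[i] * step[j])
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float("nan")
    if cov[0, 0] < 0 or cov[1, 1] < 0:
        return float("nan")
    tot = s2a + s2e
    grad = np.array([s2e, -s2a]) / (tot * tot)
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var >= 0 else float("nan")


def predict_dgv(y: np.ndarray, train_idx: np.ndarray, k: Kernel,
                vc: VarianceComponents, individuals: list[str] | None = None,
                ridge: float = RIDGE) -> DGVSet:
    """BLUP genetic values for every individual in the kernel.

    ``y`` holds the adjusted phenotypes of the training individuals (in
    kernel order restricted to ``train_idx``); phenotypes of all other
    individuals are treated as masked.  The solution is

        a_hat = sigma2_a K[:, T] (sigma2_a K_TT + sigma2_e I)^{-1} (y - mu_hat)

    which reproduces the training-set BLUPs when the mask is empty.
    """
    train_idx = np.asarray(train_idx, dtype=np.int64)
    if len(train_idx) == 0:
        raise ValueError("training set is empty")
    y = np.asarray(y, dtype=np.float64)
    if len(y) != len(train_idx):
        raise ValueError("y length must match train_idx")
    Kn, _ = _normalized(k.matrix)
    n = Kn.shape[0]
    Kr = Kn + ridge * np.eye(n)  # one consistent ridged kernel throughout
    Ktt = Kr[np.ix_(train_idx, train_idx)]
    Vtt = vc.sigma2_a * Ktt + vc.sigma2_e * np.eye(len(train_idx))
    try:
        cf = cho_factor(Vtt, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular training covariance; consider a larger diagonal ridge"
        ) from exc
    ones = np.ones(len(train_idx))
    Vi1 = cho_solve(cf, ones)
    Viy = cho_solve(cf, y)
    mu = float(ones @ Viy / (ones @ Vi1))
    resid = cho_solve(cf, y - mu)
    a_hat = vc.sigma2_a * (Kr[:, train_idx] @ resid)
    if individuals is None:
        individuals = [str(i) for i in range(n)]
    return DGVSet(individuals, a_hat)
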