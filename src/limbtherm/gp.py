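"""Gaussian-process regression with a physically fixed length scale.

The regressor maps liner-socket interface temperature ``x`` to
residual-limb skin temperature ``y`` under a squared-exponential
covariance

    C_f(x_i, x_j) = theta1 * exp(-(x_i - x_j)^2 / (2 l^2)) + sigma_n^2 delta_ij.

The defining feature of the method is that the length scale ``l`` is
*not* learned: it is clamped to the thermal time constant of the
prosthesis stack (e.g. 5.4 for a polyurethane liner with a
thermosetting socket, 6.7 for Pe-lite with thermoplastic), injecting
the materials' heat-transfer physics into an otherwise empirical model.
Only the signal variance ``theta1`` and noise ``sigma_n`` are fitted,
by maximising the log marginal likelihood (evidence) with a
quasi-Newton optimiser on log-parameters.  Note the clamp is numeric:
``l`` takes the time-constant value in minutes while ``x`` is in degC.

Targets are centred on their mean before fitting (skin temperatures sit
near 30–34 degC; a zero-mean prior would distort extrapolation) and the
offset is added back at prediction.  Predictions come with 95% bands
``mean +/- 1.96 sqrt(variance)`` where the variance includes the noise
term, i.e. the band is for noisy observations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import linalg, optimize

from .exceptions import NumericsError, ValidationError

__all__ = [
    "GPHyperparams",
    "GPModel",
    "PredictionResult",
    "sq_exp_cov",
    "log_marginal_likelihood",
    "fit",
    "predict",
    "evaluate",
]

#: Diagonal jitter ladder tried before declaring the covariance non-PD.
JITTERS = (1e-10, 1e-8, 1e-6)

#: Box bounds for theta1 and sigma_n^2 during evidence maximisation
#: (variance units, degC^2).
VARIANCE_BOUNDS = (1e-6, 1e6)

CI95_MULTIPLIER = 1.96


@dataclass(frozen=True)
class GPHyperparams:
    """Covariance hyperparameters: signal variance, length scale, noise variance."""

    theta1: float
    length_scale: float
    noise_var: float

    def __post_init__(self) -> None:
        if not self.theta1 > 0:
            raise ValidationError("theta1 must be > 0")
        if not self.length_scale > 0:
            raise ValidationError("length_scale must be > 0")
        if self.noise_var < 0:
            raise ValidationError("noise_var must be >= 0")


@dataclass
class GPModel:
    """A fitted GP: training data, hyperparameters and cached factorization."""

    train_x: np.ndarray
    train_y: np.ndarray
    hyper: GPHyperparams
    mean_offset: float
    log_marginal_likelihood: float
    chol_lower: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)
    jitter: float = 0.0


@dataclass(frozen=True)
class PredictionResult:
    mean: np.ndarray
    variance: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray


def sq_exp_cov(
    x_a: np.ndarray,
    x_b: np.ndarray,
    hyper: GPHyperparams,
    add_noise_diag: bool = False,
) -> np.ndarray:
    """Squared-exponential covariance matrix between two input vectors.

    Element (i, j) is ``theta1 * exp(-(x_a[i]-x_b[j])^2 / (2 l^2))``;
    when ``add_noise_diag`` is set (valid only for identical inputs) the
    noise variance is added on the diagonal, implementing the
    Kronecker-delta term.
    """
    a = np.asarray(x_a, dtype=float).ravel()
    b = np.asarray(x_b, dtype=float).ravel()
    d2 = (a[:, None] - b[None, :]) ** 2
    K = hyper.theta1 * np.exp(-d2 / (2.0 * hyper.length_scale**2))
    if add_noise_diag:
        if a.shape != b.shape or not np.array_equal(a, b):
            raise ValidationError("add_noise_diag requires identical input vectors")
        K[np.diag_indices_from(K)] += hyper.noise_var
    return K


def _cholesky_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    for jitter in JITTERS:
        try:
            L = linalg.cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
            return L, jitter
        except linalg.LinAlgError:
            continue
    eigmin = float(np.linalg.eigvalsh(K).min())
    raise NumericsError(
        f"training covariance is not positive definite even with jitter "
        f"{JITTERS[-1]:g}; smallest eigenvalue ~ {eigmin:.3g}"
    )


def _lml_from_factorization(L: np.ndarray, alpha: np.ndarray, y_centred: np.ndarray) -> float:
    n = y_centred.size
    return float(
        -0.5 * y_centred @ alpha
        - np.log(np.diag(L)).sum()
        - 0.5 * n * np.log(2.0 * np.pi)
    )


def log_marginal_likelihood(model: GPModel) -> float:
    """Evidence of the training targets under the stored factorization.

    Returns ``-1/2 y^T C_N^{-1} y - 1/2 log|C_N| - N/2 log 2pi`` on the
    mean-centred targets.
    """
    yc = model.train_y - model.mean_offset
    return _lml_from_factorization(model.chol_lower, model.alpha, yc)


def _nll_and_grad(
    log_params: np.ndarray, D2: np.ndarray, yc: np.ndarray, l: float
) -> tuple[float, np.ndarray]:
    theta1, noise_var = np.exp(log_params)
    n = yc.size
    E = np.exp(-D2 / (2.0 * l * l))
    K = theta1 * E + noise_var * np.eye(n)
    L, _ = _cholesky_with_jitter(K)
    alpha = linalg.cho_solve((L, True), yc)
    nll = 0.5 * yc @ alpha + np.log(np.diag(L)).sum() + 0.5 * n * np.log(2.0 * np.pi)
    Kinv = linalg.cho_solve((L, True), np.eye(n))
    # d nll / d log theta = 1/2 tr((K^{-1} - alpha alpha^T) dK/dtheta) * theta
    g_theta1 = 0.5 * theta1 * (np.sum(Kinv * E) - alpha @ (E @ alpha))
    g_noise = 0.5 * noise_var * (np.trace(Kinv) - alpha @ alpha)
    return float(nll), np.array([g_theta1, g_noise])


def _build_model(
    x: np.ndarray, y: np.ndarray, hyper: GPHyperparams
) -> GPModel:
    offset = float(y.mean())
    yc = y - offset
    K = sq_exp_cov(x, x, hyper, add_noise_diag=True)
    L, jitter = _cholesky_with_jitter(K)
    alpha = linalg.cho_solve((L, True), yc)
    return GPModel(
        train_x=x,
        train_y=y,
        hyper=hyper,
        mean_offset=offset,
        log_marginal_likelihood=_lml_from_factorization(L, alpha, yc),
        chol_lower=L,
        alpha=alpha,
        jitter=jitter,
    )


def fit(
    train_x: np.ndarray,
    train_y: np.ndarray,
    fixed_length_scale: float,
    init: GPHyperparams | None = None,
    optimizer_options: Mapping | None = None,
) -> GPModel:
    """Fit theta1 and sigma_n by evidence maximisation with ``l`` clamped.

    The length scale is held exactly at ``fixed_length_scale`` (the
    prosthesis stack's thermal time constant); the remaining two
    hyperparameters are optimised in log space with L-BFGS-B using
    analytic evidence gradients.  The returned model's evidence is never
    below the evidence at the initial hyperparameters.
    """
    x = np.asarray(train_x, dtype=float).ravel()
    y = np.asarray(train_y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("train_x and train_y must have equal length")
    if x.size < 2:
        raise ValidationError("at least 2 training pairs are required")
    if not fixed_length_scale > 0:
        raise ValidationError("fixed_length_scale must be > 0")
    if np.ptp(x) == 0:
        raise ValidationError("train_x is constant; the input carries no information")

    if init is None:
        init = GPHyperparams(theta1=1.0, length_scale=fixed_length_scale, noise_var=0.01)
    opts = {"maxiter": 200, "gtol": 1e-6}
    if optimizer_options:
        opts.update(optimizer_options)

    yc = y - y.mean()
    D2 = (x[:, None] - x[None, :]) ** 2
    p0 = np.log([init.theta1, max(init.noise_var, VARIANCE_BOUNDS[0])])
    log_bounds = [(np.log(VARIANCE_BOUNDS[0]), np.log(VARIANCE_BOUNDS[1]))] * 2
    res = optimize.minimize(
        _nll_and_grad,
        p0,
        args=(D2, yc, fixed_length_scale),
        jac=True,
        method="L-BFGS-B",
        bounds=log_bounds,
        options=opts,
    )
    if not np.all(np.isfinite(res.x)):
        raise NumericsError(f"hyperparameter optimisation diverged; last iterate {res.x}")
    nll0, _ = _nll_and_grad(p0, D2, yc, fixed_length_scale)
    best = res.x if res.fun <= nll0 else p0  # never accept a worse evidence
    theta1, noise_var = np.exp(best)
    hyper = GPHyperparams(
        theta1=float(theta1),
        length_scale=float(fixed_length_scale),
        noise_var=float(noise_var),
    )
    return _build_model(x, y, hyper)


def predict(model: GPModel, test_x: np.ndarray) -> PredictionResult:
    """Posterior mean, predictive variance and 95% band at the test inputs.

    The variance is ``(theta1 + sigma_n^2) - k_*^T C_N^{-1} k_*`` — the
    predictive variance of a *noisy* observation, bounded above by the
    prior variance ``theta1 + sigma_n^2``.
    """
    xs = np.asarray(test_x, dtype=float).ravel()
    Ks = sq_exp_cov(xs, model.train_x, model.hyper)  # (m, n)
    mean = Ks @ model.alpha + model.mean_offset
    V = linalg.cho_solve((model.chol_lower, True), Ks.T)  # (n, m)
    prior_var = model.hyper.theta1 + model.hyper.noise_var
    variance = prior_var - np.einsum("ij,ji->i", Ks, V)
    variance = np.maximum(variance, 0.0)
    half = CI95_MULTIPLIER * np.sqrt(variance)
    return PredictionResult(
        mean=mean, variance=variance, ci95_low=mean - half, ci95_high=mean + half
    )


def evaluate(pred: PredictionResult, actual: np.ndarray) -> dict[str, float]:
    """Accuracy metrics of a prediction against observed skin temperatures.

    Returns the maximum absolute error and RMSE of the posterior mean,
    and the fraction of observations inside the 95% band.
    """
    a = np.asarray(actual, dtype=float).ravel()
    if a.size != pred.mean.size:
        raise ValidationError(
            f"length mismatch: {a.size} actual vs {pred.mean.size} predicted"
        )
    err = pred.mean - a
    inside = (a >= pred.ci95_low) & (a <= pred.ci95_high)
    return {
        "max_abs_err": float(np.max(np.abs(err))),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "ci95_coverage": float(inside.mean()),
    }
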