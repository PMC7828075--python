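"""Subject-level spectral model inversion by variational Laplace.

The observed feature vector stacks the real and imaginary parts of the
in-band BOLD cross-spectral density.  The likelihood is Gaussian with a
single log-precision hyperparameter (updated in closed form each outer
iteration); the eight free parameters -- four connectivity log-scalings and
four noise hyperparameters -- carry Gaussian priors, and the posterior is the
fixed-form Gaussian that maximizes the Laplace free energy

    F = accuracy - complexity
      = E_q[log p(y | theta)] - KL(q(theta) || p(theta)),

climbed with Gauss-Newton steps under Levenberg-Marquardt damping.  Noise
amplitudes are parameterized as log scaling factors of the module defaults
(the same convention the connections use) and spectral exponents are kept in
(0, 3) by a scaled-logistic reparameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .dcm_model import (A_E_DEFAULT, A_V_DEFAULT, CrossSpectrum, DCMParams,
                        StabilityError, predict_csd)

PARAM_NAMES = ("ee_dacc_to_ai", "ee_ai_to_dacc", "ie_dacc", "ie_ai",
               "log_av_scale", "u_bv", "log_ae_scale", "u_be")
N_FREE = len(PARAM_NAMES)

B_MAX = 3.0  # spectral exponents live in (0, B_MAX)


def _u_from_exponent(b: float) -> float:
    return float(logit(b / B_MAX))


def _exponent_from_u(u: np.ndarray) -> np.ndarray:
    return B_MAX * expit(u)


# Prior SD of the exponent at its mode (b = 1) is 0.5 by the delta method:
# db/du = B_MAX * sig * (1 - sig) = 2/3 at b = 1, so var_u = (0.5 / (2/3))^2.
U_PRIOR_MEAN = _u_from_exponent(1.0)
U_PRIOR_VAR = 0.5625


@dataclass(frozen=True)
class PriorSpec:
    """Diagonal Gaussian prior over the free parameter vector."""

    mean: np.ndarray = field(default_factory=lambda: np.array(
        [0.0, 0.0, 0.0, 0.0, 0.0, U_PRIOR_MEAN, 0.0, U_PRIOR_MEAN]))
    var: np.ndarray = field(default_factory=lambda: np.array(
        [1 / 16, 1 / 16, 1 / 16, 1 / 16, 0.25, U_PRIOR_VAR, 0.25, U_PRIOR_VAR]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "var", np.asarray(self.var, float))
        if self.mean.shape != (N_FREE,) or self.var.shape != (N_FREE,):
            raise ValueError(f"prior must have {N_FREE} entries")
        if np.any(self.var <= 0):
            raise ValueError("prior covariance must be positive definite")


@dataclass
class InversionSettings:
    max_iter: int = 64
    tol_nats: float = 1e-4
    fd_step: float = 1e-3
    init_damping: float = 1.0
    lambda_fixed: float | None = None   # freeze the likelihood log-precision


@dataclass
class SubjectPosterior:
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    n_iterations: int
    converged: bool
    log_precision: float
    f_history: np.ndarray = field(repr=False, default=None)
    names: tuple = PARAM_NAMES


@dataclass
class FreeEnergyParts:
    total: float
    accuracy: float
    complexity: float


class ConvergenceError(RuntimeError):
    pass


def params_from_vector(p: np.ndarray, base: DCMParams | None = None) -> DCMParams:
    """Map the free parameter vector onto a full generative parameter set."""
    if base is None:
        base = DCMParams()
    p = np.asarray(p, float)
    a_v0 = base.noise_state[0] if base.noise_state[0] > 0 else A_V_DEFAULT
    a_e0 = base.noise_obs[0] if base.noise_obs[0] > 0 else A_E_DEFAULT
    return replace(base,
                   theta_ee=(p[0], p[1]), theta_ie=(p[2], p[3]),
                   noise_state=(a_v0 * np.exp(p[4]), float(_exponent_from_u(p[5]))),
                   noise_obs=(a_e0 * np.exp(p[6]), float(_exponent_from_u(p[7]))))


def vector_from_params(params: DCMParams, base: DCMParams | None = None) -> np.ndarray:
    if base is None:
        base = DCMParams()
    return np.array([*params.theta_ee, *params.theta_ie,
                     np.log(params.noise_state[0] / base.noise_state[0]),
                     _u_from_exponent(params.noise_state[1]),
                     np.log(params.noise_obs[0] / base.noise_obs[0]),
                     _u_from_exponent(params.noise_obs[1])])


def csd_features(csd: CrossSpectrum) -> np.ndarray:
    """Stack [Re S11, Re S22, Re S12, Im S12] over frequencies."""
    v = csd.values
    return np.concatenate([v[:, 0, 0].real, v[:, 1, 1].real,
                           v[:, 0, 1].real, v[:, 0, 1].imag])


def feature_weights(observed: CrossSpectrum) -> np.ndarray:
    """Per-feature normalization for the Gaussian likelihood.

    Welch estimates have sampling SD proportional to the spectral level, so
    entries are scaled by the observed mean autospectrum at their frequency
    (variance stabilization).  With this scaling a single likelihood
    precision is a reasonable model for all stacked entries.
    """
    scale = 0.5 * (observed.values[:, 0, 0].real + observed.values[:, 1, 1].real)
    scale = np.maximum(scale, 1e-300)
    return np.tile(scale, 4)


def _predictor(freqs: np.ndarray, base: DCMParams,
               weights: np.ndarray | None = None):
    def predict(p: np.ndarray) -> np.ndarray | None:
        try:
            g = csd_features(predict_csd(params_from_vector(p, base), freqs))
        except (StabilityError, FloatingPointError):
            return None
        if not np.all(np.isfinite(g)):
            return None
        return g if weights is None else g / weights
    return predict


def _fd_jacobian(predict, p: np.ndarray, step: float) -> np.ndarray | None:
    cols = []
    for i in range(p.size):
        dp = np.zeros_like(p)
        dp[i] = step
        gp, gm = predict(p + dp), predict(p - dp)
        if gp is None or gm is None:
            return None
        cols.append((gp - gm) / (2.0 * step))
    return np.column_stack(cols)


def _kl_gaussian(mu, cov, m0, var0) -> float:
    prec0 = 1.0 / var0
    d = mu.size
    _, logdet_cov = np.linalg.slogdet(cov)
    return 0.5 * (np.sum(prec0 * np.diag(cov))
                  + np.sum(prec0 * (mu - m0) ** 2) - d
                  + np.sum(np.log(var0)) - logdet_cov)


def _accuracy(lam: float, err: np.ndarray, jac: np.ndarray,
              cov: np.ndarray) -> float:
    n = err.size
    trace = float(np.sum((jac @ cov) * jac))
    return -0.5 * n * np.log(2 * np.pi) + 0.5 * n * lam \
        - 0.5 * np.exp(lam) * (err @ err + trace)


def variational_laplace(observed: CrossSpectrum,
                        priors: PriorSpec | None = None,
                        settings: InversionSettings | None = None,
                        base: DCMParams | None = None) -> SubjectPosterior:
    """Fit the free parameters to an observed cross-spectrum.

    Deterministic: initialization at the prior mean, no stochastic search.
    """
    priors = priors or PriorSpec()
    settings = settings or InversionSettings()
    base = base or DCMParams()
    weights = feature_weights(observed)
    predict = _predictor(observed.freqs, base, weights)
    y = csd_features(observed) / weights
    n = y.size
    m0, var0 = priors.mean, priors.var
    prec0 = np.diag(1.0 / var0)

    mu = m0.copy()
    g = predict(mu)
    if g is None:
        raise ConvergenceError("prediction non-finite at the prior mean")
    err = y - g
    if settings.lambda_fixed is not None:
        lam = settings.lambda_fixed
    else:
        lam = float(-np.log(np.mean(err**2) + 1e-300))

    jac = _fd_jacobian(predict, mu, settings.fd_step)
    if jac is None:
        raise ConvergenceError("Jacobian non-finite at the prior mean")

    def posterior_cov(jacobian, lam_):
        h = np.exp(lam_) * jacobian.T @ jacobian + prec0
        cov = np.linalg.inv(h)
        return 0.5 * (cov + cov.T), h

    cov, h = posterior_cov(jac, lam)
    f_cur = _accuracy(lam, err, jac, cov) - _kl_gaussian(mu, cov, m0, var0)
    history = [f_cur]
    damping = settings.init_damping
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        grad = np.exp(lam) * jac.T @ err - prec0 @ (mu - m0)
        improved = False
        for _ in range(12):
            with np.errstate(over="ignore", invalid="ignore"):
                step = np.linalg.solve(h + damping * np.diag(np.diag(h)), grad)
            if not np.all(np.isfinite(step)):
                damping *= 4.0
                if damping > 1e8:
                    break
                continue
            mu_new = mu + step
            g_new = predict(mu_new)
            if g_new is not None:
                err_new = y - g_new
                jac_new = _fd_jacobian(predict, mu_new, settings.fd_step)
                if jac_new is not None:
                    cov_new, h_new = posterior_cov(jac_new, lam)
                    f_new = _accuracy(lam, err_new, jac_new, cov_new) \
                        - _kl_gaussian(mu_new, cov_new, m0, var0)
                    if np.isfinite(f_new) and f_new > f_cur:
                        improved = True
                        break
            damping *= 4.0
            if damping > 1e8:
                break
        if not improved:
            converged = True
            break
        mu, err, jac, cov, h = mu_new, err_new, jac_new, cov_new, h_new
        damping = max(damping / 2.0, 1e-8)
        if settings.lambda_fixed is None:
            trace = float(np.sum((jac @ cov) * jac))
            lam_new = float(np.log(n) - np.log(err @ err + trace + 1e-300))
            cov_try, h_try = posterior_cov(jac, lam_new)
            f_try = _accuracy(lam_new, err, jac, cov_try) \
                - _kl_gaussian(mu, cov_try, m0, var0)
            if np.isfinite(f_try) and f_try >= f_cur:
                lam, cov, h = lam_new, cov_try, h_try
                f_new = f_try
            else:
                f_new = _accuracy(lam, err, jac, cov) \
                    - _kl_gaussian(mu, cov, m0, var0)
        else:
            f_new = _accuracy(lam, err, jac, cov) - _kl_gaussian(mu, cov, m0, var0)
        delta = f_new - f_cur
        f_cur = max(f_new, f_cur)
        history.append(f_cur)
        if abs(delta) < settings.tol_nats:
            converged = True
            break
    if not np.all(np.isfinite(cov)):
        raise ConvergenceError("posterior covariance non-finite "
                               f"(iteration {it}, damping {damping:.2g})")
    return SubjectPosterior(mean=mu, cov=cov, free_energy=float(f_cur),
                            n_iterations=it, converged=converged,
                            log_precision=float(lam),
                            f_history=np.array(history))


def free_energy(posterior: SubjectPosterior, observed: CrossSpectrum,
                priors: PriorSpec | None = None,
                base: DCMParams | None = None,
                fd_step: float = 1e-3) -> FreeEnergyParts:
    """Recompute F = accuracy - complexity at a given posterior."""
    priors = priors or PriorSpec()
    base = base or DCMParams()
    cov = np.asarray(posterior.cov, float)
    sign, _ = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("posterior covariance must be positive definite")
    weights = feature_weights(observed)
    predict = _predictor(observed.freqs, base, weights)
    y = csd_features(observed) / weights
    g = predict(posterior.mean)
    if g is None:
        raise ValueError("prediction non-finite at the posterior mean")
    jac = _fd_jacobian(predict, posterior.mean, fd_step)
    acc = _accuracy(posterior.log_precision, y - g, jac, cov)
    comp = _kl_gaussian(posterior.mean, cov, priors.mean, priors.var)
    return FreeEnergyParts(total=acc - comp, accuracy=acc, complexity=comp)
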