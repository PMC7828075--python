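"""Group-level parametric empirical Bayes over subject DCM posteriors.

The second level is a Gaussian hierarchical model: each subject's four free
connectivity log-scalings are a linear function of the group design (group
code, centred GLU, GLU x group, centred GSH, GSH x group, constant) plus
i.i.d. between-subject random effects with a shared unknown precision.
Subject-level posterior means enter as data with their posterior covariance,
so the model for subject i's estimate mu_i is

    mu_i ~ N(B' x_i, Sigma_i + exp(-gamma) I)

with a Gaussian prior on the effect matrix B and on the log-precision gamma.
B is conjugate given gamma and is integrated out in closed form; gamma is
optimized and given a Laplace correction, yielding the second-level free
energy used for model comparison.  Reduced models (e.g. the group-only model)
are scored by Bayesian model reduction: shrink the pruned effects' prior
variance to zero and evaluate the change in evidence analytically from the
full posterior, without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dcm_model import CONNECTION_NAMES

DESIGN_COLUMNS = ("group", "glu_centered", "glu_by_group",
                  "gsh_centered", "gsh_by_group", "constant")

# Priors: second-level effects shrink toward zero with the same variance as
# the first-level connectivity priors; the between-subject log-precision
# prior expects random effects an order of magnitude tighter than that.
EFFECT_PRIOR_VAR = 1.0 / 16.0
GAMMA_PRIOR_MEAN = np.log(16.0)
GAMMA_PRIOR_VAR = 1.0


def build_peb_design(table: pd.DataFrame) -> pd.DataFrame:
    """Second-level design matrix from a metabolite table.

    Group is coded +1 (FES) / -1 (HC); GLU and GSH are mean-centred across
    the pooled sample; interactions are elementwise products of the group
    code and the centred metabolite; the constant column of ones comes last.
    """
    groups = set(table["group"])
    if groups != {"HC", "FES"}:
        raise ValueError(f"need exactly the two groups HC and FES, got {groups}")
    code = np.where(table["group"].to_numpy() == "FES", 1.0, -1.0)
    glu_c = table["glu"].to_numpy(float) - table["glu"].mean()
    gsh_c = table["gsh"].to_numpy(float) - table["gsh"].mean()
    x = np.column_stack([code, glu_c, code * glu_c, gsh_c, code * gsh_c,
                         np.ones(len(table))])
    return pd.DataFrame(x, columns=list(DESIGN_COLUMNS),
                        index=table["subject_id"].to_numpy())


@dataclass
class PEBResult:
    """Posterior over the covariate-by-connection effect matrix.

    ``beta`` rows follow DESIGN_COLUMNS, columns CONNECTION_NAMES.  The
    covariance is over vec(beta) stacked connection-by-connection (column
    major), i.e. element (j, k) of beta sits at index k * n_cov + j.
    """

    beta: pd.DataFrame
    cov: np.ndarray
    gamma: float                    # between-subject log-precision (point est.)
    gamma_var: float
    free_energy: float
    prior_var: np.ndarray           # diagonal prior variance over vec(beta)
    design: pd.DataFrame = field(repr=False)
    _data: dict = field(repr=False, default_factory=dict)

    @property
    def n_cov(self) -> int:
        return self.beta.shape[0]

    @property
    def n_conn(self) -> int:
        return self.beta.shape[1]

    def vec_index(self, covariate: str, connection: str) -> int:
        j = list(self.beta.index).index(covariate)
        k = list(self.beta.columns).index(connection)
        return k * self.n_cov + j

    def effect_sd(self, covariate: str, connection: str) -> float:
        i = self.vec_index(covariate, connection)
        return float(np.sqrt(self.cov[i, i]))


def _stack_subject_data(posteriors, n_conn: int):
    mus, sigmas = [], []
    for post in posteriors:
        mu = np.asarray(post.mean, float)[:n_conn]
        sigma = np.asarray(post.cov, float)[:n_conn, :n_conn]
        mus.append(mu)
        sigmas.append(sigma)
    return np.array(mus), np.array(sigmas)


def _evidence_given_gamma(gamma, mus, sigmas, design, prior_var,
                          first_prec):
    """Second-level log evidence at a fixed between-subject log-precision.

    Each subject's first-level prior over the connectivity parameters (with
    precision ``first_prec``; zero means the subject estimates enter as raw
    data) is replaced by the empirical prior N(B' x_i, exp(-gamma) I) via the
    Gaussian reduction identity; the resulting criterion is quadratic in
    vec(B), which is therefore integrated out in closed form.  Returns
    (log evidence incl. the gamma prior, posterior mean and covariance of
    vec(B)).
    """
    n_sub, n_conn = mus.shape
    n_cov = design.shape[1]
    dim = n_cov * n_conn
    w = np.exp(gamma) * np.eye(n_conn)
    _, logdet_w = np.linalg.slogdet(w)
    p0 = first_prec
    _, logdet_p0 = (0.0, 0.0) if not p0.any() else np.linalg.slogdet(p0)
    prec_b = np.diag(1.0 / prior_var)
    lin = np.zeros(dim)
    const = 0.0
    for i in range(n_sub):
        p_i = np.linalg.inv(sigmas[i])
        pr_i = p_i + w - p0
        a_i = np.linalg.inv(pr_i)
        h_i = p_i @ mus[i]
        _, logdet_pi = np.linalg.slogdet(p_i)
        _, logdet_pri = np.linalg.slogdet(pr_i)
        const += 0.5 * (logdet_w - logdet_pri - logdet_p0 + logdet_pi)
        const += 0.5 * (h_i @ a_i @ h_i - mus[i] @ h_i)
        q_i = w - w @ a_i @ w
        d_i = np.kron(np.eye(n_conn), design[i][None, :])     # (n_conn, dim)
        prec_b += d_i.T @ q_i @ d_i
        lin += d_i.T @ (w @ (a_i @ h_i))
    cov_b = np.linalg.inv(prec_b)
    cov_b = 0.5 * (cov_b + cov_b.T)
    mu_b = cov_b @ lin
    _, logdet_prec = np.linalg.slogdet(prec_b)
    log_ev = (const + 0.5 * mu_b @ prec_b @ mu_b
              - 0.5 * np.sum(np.log(prior_var)) - 0.5 * logdet_prec)
    log_ev += stats.norm.logpdf(gamma, GAMMA_PRIOR_MEAN,
                                np.sqrt(GAMMA_PRIOR_VAR))
    return log_ev, mu_b, cov_b


def fit_peb(posteriors, design: pd.DataFrame,
            prior_var: np.ndarray | float = EFFECT_PRIOR_VAR,
            gamma: float | None = None,
            first_level_prior_var: np.ndarray | float | None = "default"
            ) -> PEBResult:
    """Fit the hierarchical model over the four free connectivity parameters.

    ``posteriors`` are subject-level Gaussian posteriors whose first four
    coordinates are the connectivity log-scalings, one per design row.  The
    subject-level shrinkage prior (variance ``first_level_prior_var`` per
    connection) is replaced by the empirical group prior, so second-level
    effects are estimated free of first-level attenuation; pass ``None`` to
    treat the subject means as raw data instead.  ``gamma`` fixes the
    between-subject log-precision instead of optimizing it (used by oracles
    and reduction checks).
    """
    n_sub = len(posteriors)
    if n_sub != design.shape[0]:
        raise ValueError(f"{n_sub} posteriors but {design.shape[0]} design rows")
    n_conn = len(CONNECTION_NAMES)
    n_cov = design.shape[1]
    mus, sigmas = _stack_subject_data(posteriors, n_conn)
    x = design.to_numpy(float)
    dim = n_cov * n_conn
    if np.isscalar(prior_var) or np.asarray(prior_var).ndim == 0:
        # scale-invariant prior: one covariate SD shifts a log-scaling by at
        # most ~sqrt(prior_var), whatever the covariate's units
        col_ms = np.maximum(np.mean(x**2, axis=0), 1e-12)
        prior_var = np.tile(float(prior_var) / col_ms, n_conn)
    prior_var = np.broadcast_to(np.asarray(prior_var, float), (dim,)).copy()
    if isinstance(first_level_prior_var, str):
        from .dcm_invert import PriorSpec
        first_level_prior_var = PriorSpec().var[:n_conn]
    if first_level_prior_var is None:
        first_prec = np.zeros((n_conn, n_conn))
    else:
        flv = np.broadcast_to(np.asarray(first_level_prior_var, float),
                              (n_conn,))
        first_prec = np.diag(1.0 / flv)

    def objective(g):
        return -_evidence_given_gamma(g, mus, sigmas, x, prior_var,
                                      first_prec)[0]

    if gamma is None:
        res = optimize.minimize_scalar(objective, bounds=(-4.0, 12.0),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        g_hat = float(res.x)
        # Laplace correction from the numerical curvature of the evidence.
        h = 1e-3
        f0, fp, fm = (-objective(g_hat), -objective(g_hat + h),
                      -objective(g_hat - h))
        curv = (fp - 2.0 * f0 + fm) / h**2
        gamma_var = -1.0 / curv if curv < 0 else GAMMA_PRIOR_VAR
        laplace = 0.5 * np.log(2.0 * np.pi * gamma_var)
    else:
        g_hat = float(gamma)
        gamma_var = 0.0
        laplace = 0.0

    log_ev, mu_b, cov_b = _evidence_given_gamma(g_hat, mus, sigmas, x,
                                                prior_var, first_prec)
    beta = pd.DataFrame(mu_b.reshape(n_conn, n_cov).T,
                        index=list(design.columns),
                        columns=list(CONNECTION_NAMES)[:n_conn])
    return PEBResult(beta=beta, cov=cov_b, gamma=g_hat, gamma_var=gamma_var,
                     free_energy=float(log_ev + laplace),
                     prior_var=prior_var, design=design,
                     _data={"mus": mus, "sigmas": sigmas})


@dataclass
class ReducedModel:
    name: str
    free_energy: float
    beta: pd.DataFrame
    cov: np.ndarray


def bayesian_model_reduction(full: PEBResult, keep_columns,
                             name: str = "reduced",
                             pruned_var: float = 1e-8) -> ReducedModel:
    """Evidence and posterior of a model whose pruned covariates have their
    prior variance shrunk to ~0, computed analytically from the full fit.

    For Gaussian priors/posteriors the change in log evidence under a prior
    change (Sigma0 -> Sigma0r, zero prior means) is

        dF = 1/2 [ln|P0r| - ln|Pr|] - 1/2 [ln|P0| - ln|P|]
             + 1/2 [mur' Pr mur - mu' P mu]

    with P the posterior precision and Pr = P + P0r - P0.
    """
    keep = list(keep_columns)
    if not keep:
        raise ValueError("keep_columns must not be empty")
    unknown = set(keep) - set(full.beta.index)
    if unknown:
        raise ValueError(f"unknown design columns: {sorted(unknown)}")
    n_cov, n_conn = full.n_cov, full.n_conn
    pruned = [j for j, c in enumerate(full.beta.index) if c not in keep]
    red_var = full.prior_var.copy()
    for k in range(n_conn):
        for j in pruned:
            red_var[k * n_cov + j] = pruned_var

    p0 = np.diag(1.0 / full.prior_var)
    p0r = np.diag(1.0 / red_var)
    p = np.linalg.inv(full.cov)
    mu = full.beta.to_numpy().T.reshape(-1)
    pr = p + p0r - p0
    cov_r = np.linalg.inv(pr)
    cov_r = 0.5 * (cov_r + cov_r.T)
    mu_r = cov_r @ (p @ mu)
    _, ld_p0 = np.linalg.slogdet(p0)
    _, ld_p0r = np.linalg.slogdet(p0r)
    _, ld_p = np.linalg.slogdet(p)
    _, ld_pr = np.linalg.slogdet(pr)
    df = 0.5 * (ld_p0r - ld_pr) - 0.5 * (ld_p0 - ld_p) \
        + 0.5 * (mu_r @ pr @ mu_r - mu @ p @ mu)
    beta_r = pd.DataFrame(mu_r.reshape(n_conn, n_cov).T,
                          index=full.beta.index, columns=full.beta.columns)
    return ReducedModel(name=name, free_energy=float(full.free_energy + df),
                        beta=beta_r, cov=cov_r)


@dataclass
class ModelComparison:
    names: list[str]
    free_energies: np.ndarray
    posterior_probs: np.ndarray
    log_bayes_factors: np.ndarray      # vs the best model (<= 0)
    winner: str | None                 # flagged only if its PP > 0.95

    def as_dict(self) -> dict:
        return {
            "models": self.names,
            "free_energy": [float(f) for f in self.free_energies],
            "posterior_prob": [float(p) for p in self.posterior_probs],
            "ln_bayes_factor_vs_best": [float(b) for b in self.log_bayes_factors],
            "winner": self.winner,
        }


def compare_models(free_energies: dict) -> ModelComparison:
    """Fixed-effects Bayesian model comparison: PP_i = softmax(F_i)."""
    if len(free_energies) < 2:
        raise ValueError("need at least two models to compare")
    names = list(free_energies)
    f = np.array([free_energies[n] for n in names], float)
    if not np.all(np.isfinite(f)):
        raise ValueError("free energies must be finite")
    pp = special.softmax(f)
    ln_bf = f - f.max()
    best = names[int(np.argmax(f))]
    winner = best if pp.max() > 0.95 else None
    return ModelComparison(names=names, free_energies=f, posterior_probs=pp,
                           log_bayes_factors=ln_bf, winner=winner)


@dataclass
class EffectPP:
    covariate: str
    connection: str
    mean: float
    sd: float
    sign: int
    pp: float                          # posterior mass on the mean's side of 0


def parameter_posterior_probability(result, covariate: str,
                                    connection: str) -> EffectPP:
    """Posterior probability that an effect lies on its estimated side of zero
    (Gaussian tail from the second-level posterior mean and SD)."""
    mean = float(result.beta.loc[covariate, connection])
    if isinstance(result, PEBResult):
        sd = result.effect_sd(covariate, connection)
    else:  # ReducedModel shares the vec layout through its beta frame
        n_cov = result.beta.shape[0]
        j = list(result.beta.index).index(covariate)
        k = list(result.beta.columns).index(connection)
        sd = float(np.sqrt(result.cov[k * n_cov + j, k * n_cov + j]))
    sign = int(np.sign(mean)) if mean != 0 else 0
    pp = float(stats.norm.cdf(abs(mean) / sd)) if sd > 0 else 1.0
    if mean == 0:
        pp = 0.5
    return EffectPP(covariate=covariate, connection=connection,
                    mean=mean, sd=sd, sign=sign, pp=pp)
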