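"""Synthetic study generator.

Emulates the statistical structure of a two-group (19 first-episode
schizophrenia patients, 20 healthy controls) 7T MRS + resting-state fMRI
study: group-shifted Gaussian metabolite levels in the dACC voxel, and
per-subject two-ROI BOLD timeseries generated from the two-state neural
circuit whose free connectivity log-scalings are a linear function of group
and centred metabolite levels (the same design convention the group-level
analysis assumes), integrated through the balloon model and observed with
power-law channel noise.

Default metabolite parameters follow the posterior baselines of the study
design being emulated (GLU ~ 6.64 mM, GSH ~ 1.60 mM grand means with
residual SDs 1.374 and 0.374 mM); default connectivity effects place a
moderate patient-specific metabolite coupling on the inhibitory connections:
inhibition decreasing with GLU in the dACC and increasing with GSH in both
regions, each split evenly between a main effect and a group interaction so
the coupling is present in patients and absent in controls.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dcm_model import (CONNECTION_NAMES, F_MIN, DCMParams, StabilityError,
                        bold_nonlinear, neural_jacobian)
from .peb import DESIGN_COLUMNS, build_peb_design

DT_DEFAULT = 0.05  # Euler-Maruyama step (s): >= 20 steps per TR


def substream(seed: int, *names) -> np.random.Generator:
    """Named, reproducible child stream of a master seed."""
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(
        np.random.SeedSequence(int(seed) & 0x7FFFFFFF, spawn_key=key))


@dataclass
class GroupEffects:
    """True second-level effects: design covariates x free connections.

    Entries are dimensionless shifts of the connectivity log-scalings per
    unit of the (centred, mM-scaled) covariate.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (len(DESIGN_COLUMNS), len(CONNECTION_NAMES)):
            raise ValueError(
                f"effects matrix must be {len(DESIGN_COLUMNS)} x "
                f"{len(CONNECTION_NAMES)}, got {self.matrix.shape}")

    BASELINE_IE = -0.5

    @classmethod
    def null(cls) -> "GroupEffects":
        """All second-level effects zero (no baseline shift either)."""
        return cls(np.zeros((len(DESIGN_COLUMNS), len(CONNECTION_NAMES))))

    @classmethod
    def study_null(cls) -> "GroupEffects":
        """No metabolite or group effects, but the study baseline on
        inhibition (constant row) -- the null condition matched to
        ``study_default`` for model-selection calibration."""
        eff = cls.null()
        rows = {r: j for j, r in enumerate(DESIGN_COLUMNS)}
        cols = {c: k for k, c in enumerate(CONNECTION_NAMES)}
        for conn in ("ie_dacc", "ie_ai"):
            eff.matrix[rows["constant"], cols[conn]] = cls.BASELINE_IE
        return eff

    @classmethod
    def study_default(cls) -> "GroupEffects":
        """Patient-specific metabolite couplings on intrinsic inhibition:
        in the FES group inhibition falls with GLU in the dACC (slope
        -0.4 /mM, about -0.55 log-scaling units per GLU SD) and rises with
        GSH in both regions (+1.2 /mM, about +0.45 per GSH SD); both are
        split evenly between a main effect and a group interaction so the
        coupling vanishes in controls.  Sized so the implied second-level
        z-scores at n = 39 are ~3: effects the study design can detect,
        emulating a cohort in which the reported couplings are present.
        The constant row places the cohort baseline inhibition scaling at
        -0.5, which puts the E/I resonance mid-band so the metabolite-driven
        excursions stay inside the estimator's linear range."""
        eff = cls.study_null()
        m = eff.matrix
        cols = {c: k for k, c in enumerate(CONNECTION_NAMES)}
        rows = {r: j for j, r in enumerate(DESIGN_COLUMNS)}
        m[rows["glu_centered"], cols["ie_dacc"]] = -0.2
        m[rows["glu_by_group"], cols["ie_dacc"]] = -0.2
        for conn in ("ie_dacc", "ie_ai"):
            m[rows["gsh_centered"], cols[conn]] = 0.6
            m[rows["gsh_by_group"], cols[conn]] = 0.6
        return eff

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(DESIGN_COLUMNS),
                            columns=list(CONNECTION_NAMES))


@dataclass
class StudyConfig:
    """Generative description of one synthetic study."""

    n_hc: int = 20
    n_fes: int = 19
    metabolite_means: dict = field(default_factory=lambda: {
        "glu": {"HC": 6.438, "FES": 6.844},
        "gsh": {"HC": 1.486, "FES": 1.722},
    })
    metabolite_sds: dict = field(default_factory=lambda: {
        "glu": 1.374, "gsh": 0.374,
    })
    beta_true: GroupEffects = field(default_factory=GroupEffects.study_default)
    subject_param_sd: float = 0.1
    n_vol: int = 360
    tr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_fes < 2:
            raise ValueError("need at least two subjects per group")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_vol < 64:
            raise ValueError("n_vol must be at least 64")
        for met, sd in self.metabolite_sds.items():
            if sd < 0:
                raise ValueError(f"negative SD for {met}")
        if self.subject_param_sd < 0:
            raise ValueError("subject_param_sd must be nonnegative")
        if isinstance(self.beta_true, np.ndarray):
            self.beta_true = GroupEffects(self.beta_true)

    def to_yaml(self, path) -> None:
        payload = {
            "n_hc": self.n_hc, "n_fes": self.n_fes,
            "metabolite_means": self.metabolite_means,
            "metabolite_sds": self.metabolite_sds,
            "beta_true": self.beta_true.matrix.tolist(),
            "subject_param_sd": self.subject_param_sd,
            "n_vol": self.n_vol, "tr": self.tr, "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["beta_true"] = GroupEffects(np.asarray(payload["beta_true"]))
        return cls(**payload)


def simulate_metabolites(config: StudyConfig) -> pd.DataFrame:
    """Draw a metabolite table (subject_id, group, glu, gsh) for the cohort."""
    rng = substream(config.seed, "metabolites")
    rows = []
    for group, n in (("HC", config.n_hc), ("FES", config.n_fes)):
        for i in range(n):
            row = {"subject_id": f"{group}{i + 1:03d}", "group": group}
            for met in ("glu", "gsh"):
                mean = config.metabolite_means[met][group]
                sd = config.metabolite_sds[met]
                row[met] = float(rng.normal(mean, sd))
            rows.append(row)
    table = pd.DataFrame(rows)
    if (table[["glu", "gsh"]].to_numpy() <= 0).any():
        # Truncate at a small positive floor; with study-scale means this is
        # a many-sigma event and leaves the Gaussian structure intact.
        table[["glu", "gsh"]] = table[["glu", "gsh"]].clip(lower=1e-6)
    return table


def make_subject_params(table: pd.DataFrame, beta_true: GroupEffects,
                        subject_param_sd: float, seed: int,
                        base: DCMParams | None = None) -> list[DCMParams]:
    """Per-subject generative parameters implied by the group-level model.

    Each subject's four free log-scalings are (design row) . beta_true plus
    Gaussian between-subject deviations; all other parameters take the module
    defaults.  The design row is built by the group-level module itself so
    generation and analysis share one coding convention.
    """
    if len(table) == 0:
        raise ValueError("empty metabolite table")
    if base is None:
        base = DCMParams()
    design = build_peb_design(table)
    theta = design.to_numpy() @ beta_true.matrix
    rng = substream(seed, "subject_params")
    theta = theta + rng.normal(0.0, subject_param_sd, size=theta.shape)
    return [base.with_connectivity(theta[i]) for i in range(len(table))]


def _powerlaw_noise(rng: np.random.Generator, n: int, dt: float,
                    amplitude: float, exponent: float,
                    n_series: int = 1,
                    f_floor: float = F_MIN) -> np.ndarray:
    """Gaussian series whose two-sided PSD is amplitude * f**(-exponent).

    Spectral synthesis: independent complex-Gaussian Fourier coefficients
    scaled so the periodogram expectation matches the target PSD; the DC
    component is zero.  Below ``f_floor`` (the bottom of the analysis band)
    the PSD saturates at its floor value: the power law is only identified
    in band, and an unbounded 1/f tail would push arbitrarily long
    simulations out of the hemodynamic model's stable operating range.
    Returns (n_series, n).
    """
    if amplitude == 0.0:
        return np.zeros((n_series, n))
    freqs = np.fft.rfftfreq(n, dt)
    psd = np.zeros_like(freqs)
    psd[1:] = amplitude * np.maximum(freqs[1:], f_floor) ** (-exponent)
    # periodogram expectation (one-sided, scipy convention) = 2 x the
    # two-sided target PSD
    scale = np.sqrt(n * psd / (2.0 * dt))
    coeff = scale * (rng.standard_normal((n_series, freqs.size))
                     + 1j * rng.standard_normal((n_series, freqs.size)))
    coeff[:, 0] = 0.0
    if n % 2 == 0:  # real Nyquist bin
        coeff[:, -1] = np.sqrt(2.0) * coeff[:, -1].real
    return np.fft.irfft(coeff, n=n, axis=1)


def _simulate_cohort_bold(params_list, n_vol: int, tr: float, seeds,
                          dt: float = DT_DEFAULT) -> np.ndarray:
    """Euler-Maruyama integration of a batch of subjects; returns
    (n_subjects, n_vol, 2) BOLD arrays sampled at the end of each TR."""
    n_sub = len(params_list)
    steps_per_tr = int(round(tr / dt))
    if abs(steps_per_tr * dt - tr) > 1e-9:
        raise ValueError("tr must be an integer multiple of dt")
    n_steps = n_vol * steps_per_tr

    jacobians = np.empty((n_sub, 4, 4))
    for i, params in enumerate(params_list):
        eigs = np.linalg.eigvals(neural_jacobian(params))
        worst = eigs[np.argmax(eigs.real)]
        if worst.real >= 0:
            raise StabilityError(
                f"subject {i}: unstable neural Jacobian, eigenvalue {worst:.4g}")
        jacobians[i] = neural_jacobian(params)

    hemo = params_list[0].hemo
    state_noise = np.empty((n_sub, 4, n_steps))
    obs_noise = np.empty((n_sub, n_vol, 2))
    for i, (params, seed) in enumerate(zip(params_list, seeds)):
        rng = substream(seed, "bold_state")
        a_v, b_v = params.noise_state
        state_noise[i] = _powerlaw_noise(rng, n_steps, dt, a_v, b_v, n_series=4)
        rng_obs = substream(seed, "bold_obs")
        a_e, b_e = params.noise_obs
        obs_noise[i] = _powerlaw_noise(rng_obs, n_vol, tr, a_e, b_e,
                                       n_series=2).T

    x = np.zeros((n_sub, 4))
    s = np.zeros((n_sub, 2))
    f = np.ones((n_sub, 2))
    v = np.ones((n_sub, 2))
    q = np.ones((n_sub, 2))
    inv_tau = 1.0 / hemo.tau
    inv_alpha = 1.0 / hemo.alpha
    e0 = hemo.e0
    bold = np.empty((n_sub, n_vol, 2))
    vol = 0
    for t in range(n_steps):
        xe = x[:, (0, 2)]
        dx = np.einsum("bij,bj->bi", jacobians, x) + state_noise[:, :, t]
        ds = xe - hemo.kappa * s - hemo.gamma * (f - 1.0)
        df = s
        v_pow = v ** inv_alpha
        dv = (f - v_pow) * inv_tau
        extraction = 1.0 - (1.0 - e0) ** (1.0 / f)
        dq = (f * extraction / e0 - v_pow / v * q) * inv_tau
        x = x + dt * dx
        s = s + dt * ds
        # inflow, volume and deoxyhemoglobin are physically positive; floor
        # them so rare large excursions cannot step outside the model domain
        f = np.maximum(f + dt * df, 0.01)
        v = np.maximum(v + dt * dv, 0.01)
        q = np.maximum(q + dt * dq, 0.01)
        if (t + 1) % steps_per_tr == 0:
            bold[:, vol, :] = bold_nonlinear(v, q, hemo)
            vol += 1
    return bold + obs_noise


def simulate_bold(params: DCMParams, n_vol: int, tr: float, seed: int,
                  dt: float = DT_DEFAULT) -> np.ndarray:
    """Simulate one subject's (n_vol, 2) BOLD pair (ROI order dACC, AI)."""
    return _simulate_cohort_bold([params], n_vol, tr, [seed], dt=dt)[0]


def simulate_cohort(table: pd.DataFrame, config: StudyConfig,
                    base: DCMParams | None = None):
    """Metabolite-coupled cohort simulation.

    Returns (params_list, bold) where bold is (n_subjects, n_vol, 2); each
    subject's BOLD stream is seeded from the master seed and the subject_id,
    so the result is independent of cohort composition and iteration order.
    """
    params_list = make_subject_params(table, config.beta_true,
                                      config.subject_param_sd, config.seed,
                                      base=base)
    seeds = [substream(config.seed, "bold", sid).integers(2**31)
             for sid in table["subject_id"]]
    bold = _simulate_cohort_bold(params_list, config.n_vol, config.tr, seeds)
    return params_list, bold


def write_metabolites_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=["subject_id", "group", "glu", "gsh"])


def write_timeseries_csv(bold: np.ndarray, tr: float, path) -> None:
    """Per-subject timeseries CSV (roi_dacc, roi_ai) with a TR sidecar JSON."""
    pd.DataFrame(bold, columns=["roi_dacc", "roi_ai"]).to_csv(path, index=False)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"tr_s": tr, "n_vol": int(bold.shape[0])}, fh)


def read_timeseries_csv(path):
    """Read a timeseries CSV and its TR sidecar; returns (data, tr)."""
    data = pd.read_csv(path)[["roi_dacc", "roi_ai"]].to_numpy(float)
    with open(str(path) + ".json") as fh:
        tr = float(json.load(fh)["tr_s"])
    return data, tr
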