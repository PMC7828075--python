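"""Generative model for two-region resting-state fMRI.

Each region (dACC, AI) is a two-state neural node: one excitatory (E) and one
inhibitory (I) population.  Free parameters are log scaling factors on the
extrinsic E->E connections between regions (default strength +1/8 Hz) and on
the intrinsic I->E connections within each region (default -1/8 Hz); the
E->I drive and the self-inhibition of every population are fixed.  Neural
activity passes through a balloon hemodynamic model (vasodilatory signal,
inflow, blood volume, deoxyhemoglobin) and a nonlinear BOLD observation
equation.  Because the neural dynamics are linear and the hemodynamics are
linearized at their resting fixed point, the model predicts the complex
cross-spectral density (CSD) of the observed BOLD pair in closed form, which
is the data feature the inversion operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

# Fixed circuit constants (1/s).  The between- and within-region default
# strengths of the free connections are 1/8 Hz.  Self-inhibition and the
# E->I drive are fixed (not estimated); their values set the operating point
# of the E/I loop.  With a strong fixed E->I drive and light self-inhibition
# the loop resonates inside the analysis band (imaginary eigenvalue part
# sqrt(0.125 * EI_FIXED) ~ 0.61 rad/s ~ 0.1 Hz), so scaling the I->E return
# path visibly moves the resonance -- this is what makes the inhibitory
# log-scalings identifiable from six minutes of band-limited data; an
# overdamped loop (e.g. self-inhibition -0.5 with a weak drive) leaves the
# symmetrised spectral divergence between clearly different inhibition
# levels below one nat, unrecoverable by any estimator.
CONN_BASE = 0.125
SELF_INHIBITION = -0.25
EI_FIXED = 3.0

N_NEURAL = 4          # [dACC_E, dACC_I, AI_E, AI_I]
N_HEMO_PER_REGION = 4  # [s, f, v, q]
N_STATES = N_NEURAL + 2 * N_HEMO_PER_REGION

REGIONS = ("dacc", "ai")
CONNECTION_NAMES = ("ee_dacc_to_ai", "ee_ai_to_dacc", "ie_dacc", "ie_ai")

# Default analysis band (Hz) and grid size.
F_MIN = 0.0078
F_MAX = 0.1
N_FREQ = 32


class StabilityError(ValueError):
    """Raised when the neural system has a non-decaying mode."""


@dataclass(frozen=True)
class HemoParams:
    """Balloon-model constants, shared by both regions.

    kappa : signal decay rate (1/s)
    gamma : autoregulatory feedback rate (1/s)
    tau   : mean transit time of the venous compartment (s)
    alpha : Grubb vessel stiffness exponent, in (0, 1)
    e0    : resting oxygen extraction fraction, in (0, 1)
    epsilon : intra/extravascular signal ratio
    v0    : resting venous blood volume fraction
    te    : echo time (s), used in the BOLD signal constants
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    e0: float = 0.4
    epsilon: float = 1.0
    v0: float = 0.04
    te: float = 0.02

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "v0", "te"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hemodynamic parameter {name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.e0 < 1:
            raise ValueError("E0 must lie in (0, 1)")

    @property
    def k1(self) -> float:
        return 4.3 * 40.3 * self.e0 * self.te

    @property
    def k2(self) -> float:
        return self.epsilon * 25.0 * self.e0 * self.te

    @property
    def k3(self) -> float:
        return 1.0 - self.epsilon


# Default endogenous-fluctuation and channel-noise hyperparameters.  The
# amplitudes are PSD levels at 1 Hz (units^2/Hz).  a_v keeps the neural
# excursions small relative to the balloon model's stable operating range
# (the inflow state reaches zero near x ~ -0.3); a_e is set so that the
# band-averaged signal-to-noise power ratio of the predicted BOLD spectra is
# approximately 4 under otherwise-default parameters.
A_V_DEFAULT = 1e-4
B_V_DEFAULT = 1.0
A_E_DEFAULT = 1.35e-7
B_E_DEFAULT = 1.0


@dataclass(frozen=True)
class DCMParams:
    """Full generative parameter set for one subject.

    ``theta_ee`` and ``theta_ie`` are log scaling factors: the effective
    extrinsic weights are ``+0.125 * exp(theta_ee)`` and the intrinsic
    inhibitory weights ``-0.125 * exp(theta_ie)``, so any finite theta keeps
    the sign of the connection (positivity/negativity constraint).
    """

    theta_ee: tuple[float, float] = (0.0, 0.0)   # (dACC->AI, AI->dACC)
    theta_ie: tuple[float, float] = (0.0, 0.0)   # (within dACC, within AI)
    hemo: HemoParams = field(default_factory=HemoParams)
    noise_state: tuple[float, float] = (A_V_DEFAULT, B_V_DEFAULT)  # (a_v, b_v)
    noise_obs: tuple[float, float] = (A_E_DEFAULT, B_E_DEFAULT)    # (a_e, b_e)

    def __post_init__(self) -> None:
        th = np.concatenate([self.theta_ee, self.theta_ie])
        if not np.all(np.isfinite(np.exp(th))):
            raise ValueError("exp(theta) must be finite")
        if self.noise_state[0] < 0 or self.noise_obs[0] < 0:
            raise ValueError("noise amplitudes must be nonnegative")

    @property
    def free_connectivity(self) -> np.ndarray:
        """The four free log-scalings in canonical order."""
        return np.array([*self.theta_ee, *self.theta_ie], float)

    def with_connectivity(self, theta: np.ndarray) -> "DCMParams":
        theta = np.asarray(theta, float)
        return replace(self, theta_ee=(theta[0], theta[1]),
                       theta_ie=(theta[2], theta[3]))


@dataclass
class CrossSpectrum:
    """Frequency-indexed 2x2 complex cross-spectral matrices.

    All spectra in this package are two-sided PSDs (units^2/Hz): a white
    series of variance sigma^2 sampled at interval tr has a flat autospectrum
    at sigma^2 * tr.
    """

    freqs: np.ndarray          # Hz, ascending
    values: np.ndarray         # (n_freq, 2, 2) complex

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.values = np.asarray(self.values, complex)
        if self.freqs.ndim != 1 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be 1-D and strictly ascending")
        if self.values.shape != (self.freqs.size, 2, 2):
            raise ValueError("values must have shape (n_freq, 2, 2)")
        herm_err = np.max(np.abs(self.values - np.conj(np.swapaxes(self.values, 1, 2))))
        if herm_err > 1e-8 * max(1.0, float(np.max(np.abs(self.values)))):
            raise ValueError("cross-spectral matrices must be Hermitian")

    def to_json(self, path) -> None:
        payload = {
            "freqs_hz": self.freqs.tolist(),
            "real": self.values.real.tolist(),
            "imag": self.values.imag.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CrossSpectrum":
        with open(path) as fh:
            payload = json.load(fh)
        values = np.asarray(payload["real"]) + 1j * np.asarray(payload["imag"])
        return cls(np.asarray(payload["freqs_hz"]), values)


def default_freq_grid(f_min: float = F_MIN, f_max: float = F_MAX,
                      n: int = N_FREQ) -> np.ndarray:
    """Logarithmically spaced analysis frequencies (Hz)."""
    return np.geomspace(f_min, f_max, n)


def neural_jacobian(params: DCMParams) -> np.ndarray:
    """4x4 coupling matrix of the E/I populations (state order
    [dACC_E, dACC_I, AI_E, AI_I]; entry [to, from], units 1/s)."""
    w_ee = CONN_BASE * np.exp(params.theta_ee)
    w_ie = CONN_BASE * np.exp(params.theta_ie)
    a = np.diag(np.full(N_NEURAL, SELF_INHIBITION))
    a[2, 0] = w_ee[0]      # dACC_E -> AI_E
    a[0, 2] = w_ee[1]      # AI_E  -> dACC_E
    a[0, 1] = -w_ie[0]     # dACC_I -> dACC_E
    a[2, 3] = -w_ie[1]     # AI_I  -> AI_E
    a[1, 0] = EI_FIXED     # dACC_E -> dACC_I
    a[3, 2] = EI_FIXED     # AI_E  -> AI_I
    return a


def _check_neural_stability(params: DCMParams) -> np.ndarray:
    a = neural_jacobian(params)
    eigs = np.linalg.eigvals(a)
    worst = eigs[np.argmax(eigs.real)]
    if worst.real >= 0:
        raise StabilityError(
            f"neural Jacobian has a non-decaying eigenvalue {worst:.4g}")
    return a


def hemodynamic_fixed_point() -> np.ndarray:
    """Resting state of the full system: x = s = 0, f = v = q = 1."""
    x0 = np.zeros(N_STATES)
    for r in range(2):
        base = N_NEURAL + r * N_HEMO_PER_REGION
        x0[base + 1 : base + 4] = 1.0  # f, v, q
    return x0


def full_system_jacobian(params: DCMParams) -> tuple[np.ndarray, np.ndarray]:
    """12x12 Jacobian of neural + balloon states, linearized at rest.

    Only the E population of each region drives its vasodilatory signal.
    Returns (J, fixed_point).
    """
    a = _check_neural_stability(params)
    h = params.hemo
    j = np.zeros((N_STATES, N_STATES))
    j[:N_NEURAL, :N_NEURAL] = a
    ln_1_e0 = np.log(1.0 - h.e0)
    for r, e_idx in enumerate((0, 2)):
        b = N_NEURAL + r * N_HEMO_PER_REGION
        s, f, v, q = b, b + 1, b + 2, b + 3
        j[s, e_idx] = 1.0
        j[s, s] = -h.kappa
        j[s, f] = -h.gamma
        j[f, s] = 1.0
        j[v, f] = 1.0 / h.tau
        j[v, v] = -1.0 / (h.alpha * h.tau)
        j[q, f] = (1.0 + (1.0 - h.e0) * ln_1_e0 / h.e0) / h.tau
        j[q, v] = -(1.0 / h.alpha - 1.0) / h.tau
        j[q, q] = -1.0 / h.tau
    return j, hemodynamic_fixed_point()


def bold_nonlinear(v: np.ndarray, q: np.ndarray, hemo: HemoParams) -> np.ndarray:
    """BOLD observation equation as a function of volume and deoxyhemoglobin."""
    return hemo.v0 * (hemo.k1 * (1.0 - q)
                      + hemo.k2 * (1.0 - q / v)
                      + hemo.k3 * (1.0 - v))


def bold_gradient(params: DCMParams) -> np.ndarray:
    """2x12 derivative of the BOLD observation w.r.t. the full state at rest.

    Nonzero only in the (v, q) columns of each region's hemodynamic block.
    """
    h = params.hemo
    grad = np.zeros((2, N_STATES))
    for r in range(2):
        b = N_NEURAL + r * N_HEMO_PER_REGION
        grad[r, b + 2] = h.v0 * (h.k2 - h.k3)           # d/dv at v=q=1
        grad[r, b + 3] = -h.v0 * (h.k1 + h.k2)          # d/dq
    return grad


def state_noise_psd(params: DCMParams, freqs: np.ndarray) -> np.ndarray:
    """Two-sided PSD of the endogenous fluctuations entering each neural state."""
    a_v, b_v = params.noise_state
    return a_v * np.asarray(freqs, float) ** (-b_v)


def observation_noise_psd(params: DCMParams, freqs: np.ndarray) -> np.ndarray:
    """Two-sided PSD of the channel noise on each BOLD signal."""
    a_e, b_e = params.noise_obs
    return a_e * np.asarray(freqs, float) ** (-b_e)


def predict_csd(params: DCMParams, freqs: np.ndarray | None = None) -> CrossSpectrum:
    """Analytic BOLD cross-spectral density of the linearized system.

    G_y(f) = L (i w I - J)^-1 B G_v(f) B^T (i w I - J)^-H L^H + G_e(f) I
    with w = 2 pi f, L the BOLD gradient and B the injection of the
    endogenous fluctuations into the four neural states.
    """
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive")
    j, _ = full_system_jacobian(params)
    lgrad = bold_gradient(params)
    omega = 2.0 * np.pi * freqs
    # (n_f, 12, 12) resolvent systems solved against the neural selector.
    systems = 1j * omega[:, None, None] * np.eye(N_STATES) - j[None]
    selector = np.zeros((N_STATES, N_NEURAL))
    selector[:N_NEURAL, :N_NEURAL] = np.eye(N_NEURAL)
    resolvent = np.linalg.solve(systems, selector[None])      # (n_f, 12, 4)
    transfer = lgrad @ resolvent                              # (n_f, 2, 4)
    g_v = state_noise_psd(params, freqs)                      # shared by states
    driven = (transfer * g_v[:, None, None]) @ np.conj(np.swapaxes(transfer, 1, 2))
    g_e = observation_noise_psd(params, freqs)
    values = driven + g_e[:, None, None] * np.eye(2)
    # enforce exact Hermitian symmetry against round-off
    values = 0.5 * (values + np.conj(np.swapaxes(values, 1, 2)))
    return CrossSpectrum(freqs, values)


def estimate_csd(data: np.ndarray, tr: float,
                 freqs: np.ndarray | None = None,
                 nperseg: int = 128) -> CrossSpectrum:
    """Welch cross-spectral estimate of a two-ROI timeseries.

    Hann window, 50% overlap, segment length ``nperseg`` samples, interpolated
    onto the requested in-band frequency grid.  ``data`` is (n_vol, 2).
    """
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("data must be (n_vol, 2)")
    n_vol = data.shape[0]
    if n_vol < nperseg:
        raise ValueError(f"need at least {nperseg} volumes, got {n_vol}")
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, float)
    fs = 1.0 / tr
    f_res = fs / nperseg
    if freqs[0] < f_res * 0.99 or freqs[-1] > fs / 2:
        raise ValueError("requested band is outside the resolvable range "
                         f"[{f_res:.4g}, {fs / 2:.4g}] Hz")
    welch_kwargs = dict(fs=fs, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, detrend="constant",
                        scaling="density", return_onesided=True)
    f_w, s00 = sp_signal.csd(data[:, 0], data[:, 0], **welch_kwargs)
    _, s11 = sp_signal.csd(data[:, 1], data[:, 1], **welch_kwargs)
    _, s01 = sp_signal.csd(data[:, 0], data[:, 1], **welch_kwargs)
    # scipy returns one-sided densities; convert to the package's two-sided
    # convention (a white series of variance s^2 is flat at s^2 * tr)
    s00, s11, s01 = 0.5 * s00, 0.5 * s11, 0.5 * s01
    values = np.empty((freqs.size, 2, 2), complex)
    values[:, 0, 0] = np.interp(freqs, f_w, s00.real)
    values[:, 1, 1] = np.interp(freqs, f_w, s11.real)
    # scipy's csd(x, y) estimates E[conj(X) Y]; the model predicts
    # E[X conj(Y)], so the cross term is conjugated.
    cross = np.interp(freqs, f_w, s01.real) - 1j * np.interp(freqs, f_w, s01.imag)
    values[:, 0, 1] = cross
    values[:, 1, 0] = np.conj(cross)
    return CrossSpectrum(freqs, values)
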