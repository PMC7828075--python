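"""Drift and confound removal for extracted ROI timeseries.

The analysis band is 0.0078-0.1 Hz.  Slow scanner drifts below the band are
modeled by discrete cosine regressors and regressed out together with any
nuisance timeseries (head motion, white matter, CSF); fluctuations inside the
band are left untouched because in-band cosine columns are orthogonal to the
sub-band drift columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dcm_model import F_MAX, F_MIN


@dataclass
class TimeseriesPair:
    """Two-ROI BOLD timeseries (column order: dACC, AI) at repetition time tr."""

    tr: float
    data: np.ndarray                      # (n_vol, 2)
    confounds: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.ndim != 2 or self.data.shape[1] != 2:
            raise ValueError("data must be (n_vol, 2)")
        if self.confounds is not None:
            self.confounds = np.asarray(self.confounds, float)
            if self.confounds.shape[0] != self.data.shape[0]:
                raise ValueError("confounds must be row-matched to data")

    @property
    def n_vol(self) -> int:
        return self.data.shape[0]


def _dct_columns(n_vol: int, ks: np.ndarray) -> np.ndarray:
    """Unit-normalized DCT-II columns cos(pi k (2t+1) / (2 n)) for the given k."""
    t = np.arange(n_vol)
    cols = np.cos(np.pi * np.outer(2 * t + 1, ks) / (2.0 * n_vol))
    return cols / np.linalg.norm(cols, axis=0)


def cosine_basis(n_vol: int, tr: float,
                 f_min: float = F_MIN, f_max: float = F_MAX) -> np.ndarray:
    """In-band discrete cosine basis.

    Column k of the full DCT corresponds to frequency k / (2 n_vol tr); the
    returned matrix keeps exactly the columns whose frequency lies in
    [f_min, f_max], unit-normalized (hence orthonormal).
    """
    if not 0 < f_min < f_max < 0.5 / tr:
        raise ValueError("need 0 < f_min < f_max < Nyquist")
    ks = np.arange(1, n_vol)
    freqs = ks / (2.0 * n_vol * tr)
    keep = ks[(freqs >= f_min) & (freqs <= f_max)]
    if keep.size == 0:
        raise ValueError("no cosine regressor falls inside the requested band")
    return _dct_columns(n_vol, keep)


def drift_basis(n_vol: int, tr: float, f_min: float = F_MIN) -> np.ndarray:
    """Cosine regressors strictly below f_min (the slow drifts to remove)."""
    ks = np.arange(1, n_vol)
    freqs = ks / (2.0 * n_vol * tr)
    keep = ks[freqs < f_min]
    if keep.size == 0:
        return np.empty((n_vol, 0))
    return _dct_columns(n_vol, keep)


def remove_confounds(ts: TimeseriesPair,
                     f_min: float = F_MIN) -> TimeseriesPair:
    """Residualize the ROI pair against drifts and nuisance regressors.

    The regression design is [constant, sub-band cosines, confounds]; the
    residual is therefore mean-centred with slow drifts and confound-spanned
    variance projected out, while in-band signal passes through unchanged.
    Idempotent: the residual of a residual is itself.
    """
    n_vol = ts.n_vol
    design_blocks = [np.ones((n_vol, 1)), drift_basis(n_vol, ts.tr, f_min)]
    if ts.confounds is not None and ts.confounds.shape[1] > 0:
        design_blocks.append(ts.confounds)
    design = np.column_stack(design_blocks)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient confound matrix; using pseudo-inverse",
                      RuntimeWarning, stacklevel=2)
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    residual = ts.data - design @ beta
    return TimeseriesPair(tr=ts.tr, data=residual, confounds=ts.confounds)
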