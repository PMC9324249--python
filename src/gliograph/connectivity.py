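"""ROI-level denoising and Fisher-z connectivity matrices.

The denoising chain mirrors a standard ROI-level resting-state pipeline:
linear detrending, optional nuisance (CSF/WM-style) regression, and a hard
band-pass between 0.01 and 0.1 Hz applied on the discrete frequency grid.
Connectivity is the Fisher-transformed Pearson correlation between every
pair of ROI series, with the correlation clipped at 1 - 1e-7 so degenerate
(perfectly collinear) synthetic inputs stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

logger = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass and denoising settings for one acquisition.

    The band must sit inside (0, Nyquist] where Nyquist = 1/(2*TR).
    """

    low_hz: float = 0.01
    high_hz: float = 0.1
    detrend: bool = True
    confound_regressors: np.ndarray | None = None

    def validate(self, TR: float) -> None:
        nyquist = 1.0 / (2.0 * TR)
        if not (0 <= self.low_hz < self.high_hz <= nyquist + 1e-12):
            raise InvalidArgumentError(
                f"band [{self.low_hz}, {self.high_hz}] outside (0, {nyquist}]"
            )


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N Fisher-z matrix; diagonal stored as 0."""

    z: np.ndarray = field(repr=False)
    t_effective: int = 0
    subject_id: str = ""

    def __post_init__(self):
        z = self.z
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise InvalidArgumentError("z must be square")
        if not np.allclose(z, z.T):
            raise InvalidArgumentError("z must be symmetric")
        if np.any(np.diag(z) != 0):
            raise InvalidArgumentError("diagonal must be stored as 0")
        if not np.all(np.isfinite(z)):
            raise InvalidArgumentError("off-diagonal entries must be finite")

    @property
    def n_roi(self) -> int:
        return self.z.shape[0]


def detrend(ts: np.ndarray) -> np.ndarray:
    """Remove each column's least-squares linear trend (and mean)."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 3:
        raise InvalidArgumentError("detrend requires T >= 3")
    from scipy.signal import detrend as _sp_detrend

    return _sp_detrend(ts, axis=0, type="linear")


def regress_confounds(ts: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residualize each column against the regressors (plus an intercept)."""
    ts = np.asarray(ts, dtype=float)
    reg = np.atleast_2d(np.asarray(regressors, dtype=float))
    if reg.shape[0] != ts.shape[0]:
        reg = reg.T
    if reg.shape[0] != ts.shape[0]:
        raise InvalidArgumentError("regressors must have T rows")
    if reg.shape[1] >= ts.shape[0]:
        raise InvalidArgumentError("need k < T regressors")
    design = np.column_stack([np.ones(ts.shape[0]), reg])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InvalidArgumentError("regressors are rank deficient")
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta


def bandpass(ts: np.ndarray, TR: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Hard frequency-domain band-pass on the discrete frequency grid.

    Components with low_hz <= f <= high_hz are retained exactly, everything
    else (including the mean when low_hz > 0) is zeroed.  Idempotent.
    """
    ts = np.asarray(ts, dtype=float)
    FilterSpec(low_hz=low_hz, high_hz=high_hz).validate(TR)
    T = ts.shape[0]
    freqs = np.fft.rfftfreq(T, d=TR)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spectrum = np.fft.rfft(ts, axis=0)
    spectrum[~keep] = 0.0
    return np.fft.irfft(spectrum, n=T, axis=0)


def correlation_matrix(ts: np.ndarray, subject_id: str = "") -> ConnectivityMatrix:
    """Fisher-z ROI-to-ROI matrix from a T x N timeseries.

    Correlations are clipped to +-(1 - 1e-7) before atanh.  Zero-variance
    columns yield a logged warning and a zeroed row/column.
    """
    ts = np.asarray(ts, dtype=float)
    T, n = ts.shape
    if T < 5:
        raise InvalidArgumentError("correlation requires T >= 5")
    sd = ts.std(axis=0)
    # Relative tolerance: a constant column stored in floats can carry
    # rounding noise of order eps * |mean|.
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(ts.mean(axis=0)))
    if degenerate.any():
        logger.warning(
            "zero-variance columns %s: connectivity row/column set to 0",
            np.flatnonzero(degenerate).tolist(),
        )
    safe = ts.copy()
    safe[:, degenerate] = np.random.default_rng(0).standard_normal((T, degenerate.sum()))
    r = np.corrcoef(safe, rowvar=False)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    z[degenerate, :] = 0.0
    z[:, degenerate] = 0.0
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, t_effective=T, subject_id=subject_id)


def connectivity_pipeline(
    ts: np.ndarray,
    TR: float,
    filter_spec: FilterSpec | None = None,
    subject_id: str = "",
) -> ConnectivityMatrix:
    """detrend -> confound regression -> band-pass -> Fisher-z correlation."""
    spec = filter_spec or FilterSpec()
    spec.validate(TR)
    out = np.asarray(ts, dtype=float)
    if spec.detrend:
        out = detrend(out)
    if spec.confound_regressors is not None:
        out = regress_confounds(out, spec.confound_regressors)
    out = bandpass(out, TR, spec.low_hz, spec.high_hz)
    return correlation_matrix(out, subject_id=subject_id)
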