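"""Pairwise synchronization estimators: SL, PLV and magnitude-squared coherence.

All three estimators return a symmetric channels x channels
:class:`ConnectivityMatrix` with entries in [0, 1] and a zero diagonal (the
diagonal is fixed to zero by convention so downstream sparsity thresholding
never selects self-edges).

Synchronization likelihood (SL)
-------------------------------
SL measures generalized synchronization between two series via time-delay
embedding.  Each channel is embedded with dimension ``m`` and lag ``l``;
for every reference time ``i`` a critical distance is chosen by exact rank
selection so that a fraction ``p_ref`` of the embedded points within the
admissible window (|i - j| > w1, the Theiler exclusion, and |i - j| <= w2)
are recurrences.  The SL between channels x and y is the fraction of x's
recurrences at time i that are simultaneously recurrences of y, averaged
over reference times:

    SL_xy = mean_i  |R_x(i) ∩ R_y(i)| / k_i ,      k_i = round(p_ref * W_i)

For independent signals the expected value is ~p_ref (the estimator's
floor); for identical signals it is 1.  Because both channels share the
same admissible window and recurrence count k_i, the statistic is exactly
symmetric.  An optional rescaling (SL - p_ref)/(1 - p_ref) is available
but off by default, since raw SL magnitudes are the conventional report.

PLV uses the analytic-signal instantaneous phase of the already band-
limited input; coherence uses Welch-averaged modified periodograms (Hann
taper, 2-s segments, 50% overlap by default) averaged over the in-band
frequency bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from distractnet.bands import BandDefinition

logger = logging.getLogger(__name__)

ESTIMATORS: tuple[str, ...] = ("SL", "PLV", "COH")


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel synchronization strengths in [0, 1]."""

    values: np.ndarray
    estimator: str
    band: str
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"values must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero by convention")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError(f"entries must lie in [0, 1], got range [{v.min()}, {v.max()}]")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}, got {self.estimator!r}")
        self.values = np.clip(v, 0.0, 1.0)
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(v.shape[0])]

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SLParams:
    """Synchronization-likelihood parameters.

    ``m`` embedding dimension, ``lag`` embedding delay in samples, ``w1``
    Theiler window (defaults to 2*lag*(m-1)), ``w2`` outer window (defaults
    to w1 + floor(n_valid / p_ref), i.e. effectively unbounded), ``p_ref``
    the reference recurrence probability, ``n_ref`` the number of evenly
    spaced reference time points the time average runs over.
    """

    m: int = 10
    lag: int = 10
    w1: int | None = None
    w2: int | None = None
    p_ref: float = 0.05
    n_ref: int = 128
    rescale: bool = False

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"embedding dimension m must be >= 2, got {self.m}")
        if self.lag < 1:
            raise ValueError(f"lag must be >= 1, got {self.lag}")
        if not 0.0 < self.p_ref < 1.0:
            raise ValueError(f"p_ref must lie in (0, 1), got {self.p_ref}")
        if self.n_ref < 2:
            raise ValueError("n_ref must be >= 2")
        if self.w1 is not None and self.w2 is not None and not self.w1 < self.w2:
            raise ValueError(f"need w1 < w2, got w1={self.w1}, w2={self.w2}")

    def resolve(self, n_valid: int) -> tuple[int, int]:
        w1 = self.w1 if self.w1 is not None else 2 * self.lag * (self.m - 1)
        w2 = self.w2 if self.w2 is not None else w1 + int(n_valid / self.p_ref)
        return w1, w2


@dataclass(frozen=True)
class SpectralParams:
    """Welch cross-spectrum parameters for the coherence estimator.

    ``segment_seconds`` is used when ``segment_length`` (samples) is unset;
    the default 2-s Hann segments with 50% overlap give 0.5 Hz resolution
    at 512 Hz.
    """

    segment_length: int | None = None
    segment_seconds: float = 2.0
    overlap: float = 0.5
    window: str = "hann"

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError(f"overlap must lie in [0, 1), got {self.overlap}")
        if self.segment_length is not None and self.segment_length < 8:
            raise ValueError("segment_length must be >= 8 samples")

    def nperseg(self, fs: float) -> int:
        return (
            self.segment_length
            if self.segment_length is not None
            else int(round(self.segment_seconds * fs))
        )


def _embed(x: np.ndarray, m: int, lag: int) -> np.ndarray:
    """Time-delay embedding: returns (n_valid, m) matrix of state vectors."""
    n_valid = len(x) - (m - 1) * lag
    idx = np.arange(n_valid)[:, None] + lag * np.arange(m)[None, :]
    return x[idx]


def _recurrence_mask(
    emb: np.ndarray,
    ref_idx: np.ndarray,
    invalid: np.ndarray,
    window: np.ndarray,
    k: np.ndarray,
) -> np.ndarray:
    """Boolean recurrence matrix R[i, j]: j is among the k_i nearest admissible
    neighbors of reference point i in the embedded space of one channel.

    Squared Euclidean distances via the Gram identity in float32 (ranking is
    invariant), critical distances by exact rank selection per row.
    """
    sq = np.einsum("ij,ij->i", emb, emb)
    d2 = sq[ref_idx][:, None] + sq[None, :] - 2.0 * (emb[ref_idx] @ emb.T)
    d2[invalid] = np.inf
    k_max = int(k.max())
    head = np.sort(np.partition(d2, k_max - 1, axis=1)[:, :k_max], axis=1)
    eps = head[np.arange(len(ref_idx)), k - 1]
    return (d2 <= eps[:, None]) & window


def sl_matrix(
    data: np.ndarray,
    params: SLParams | None = None,
    channels: Sequence[str] | None = None,
    band: str = "broadband",
) -> ConnectivityMatrix:
    """Synchronization-likelihood matrix of a channels x samples array."""
    params = params or SLParams()
    data = np.asarray(data, dtype=np.float32)
    n_ch, n_t = data.shape
    n_valid = n_t - (params.m - 1) * params.lag
    w1, w2 = params.resolve(max(n_valid, 1))
    min_len = (params.m - 1) * params.lag + w1 + 20
    if n_valid <= w1 + 20:
        raise ValueError(
            f"epoch of {n_t} samples too short for SL with m={params.m}, "
            f"lag={params.lag}, w1={w1}: need more than {min_len} samples"
        )

    n_ref = min(params.n_ref, n_valid)
    ref_idx = np.unique(np.linspace(0, n_valid - 1, n_ref).astype(int))
    n_ref = len(ref_idx)
    lags = np.abs(ref_idx[:, None] - np.arange(n_valid)[None, :])
    window = (lags > w1) & (lags <= w2)
    invalid = ~window
    w_count = window.sum(axis=1)
    k = np.maximum(np.round(params.p_ref * w_count).astype(int), 1)

    # weight each mask row by sqrt(1/k_i): SL then reduces to one Gram matmul,
    # SL_xy = (1/n_ref) sum_ij Rx_ij Ry_ij / k_i, exactly symmetric
    root_inv_k = np.sqrt(1.0 / k).astype(np.float32)
    weighted = np.empty((n_ch, n_ref * n_valid), dtype=np.float32)
    for ch in range(n_ch):
        emb = _embed(data[ch], params.m, params.lag)
        mask = _recurrence_mask(emb, ref_idx, invalid, window, k)
        weighted[ch] = (mask * root_inv_k[:, None]).ravel()
    out = (weighted @ weighted.T).astype(float) / n_ref
    np.fill_diagonal(out, 0.0)
    out = np.clip((out + out.T) / 2.0, 0.0, 1.0)  # ties can overshoot 1 marginally
    if params.rescale:
        out = np.clip((out - params.p_ref) / (1.0 - params.p_ref), 0.0, 1.0)
        np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(out, "SL", band, list(channels or []))


def plv_from_phases(phases: np.ndarray) -> np.ndarray:
    """PLV matrix from instantaneous phases (n_channels x n_times, radians).

    PLV_xy = | mean_t exp(j (phi_x(t) - phi_y(t))) |, diagonal zeroed.
    """
    phases = np.asarray(phases, dtype=float)
    n_t = phases.shape[1]
    z = np.exp(1j * phases)
    plv = np.abs(z @ z.conj().T) / n_t
    np.fill_diagonal(plv, 0.0)
    return np.clip((plv + plv.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry


def plv_matrix(
    data: np.ndarray,
    channels: Sequence[str] | None = None,
    band: str = "broadband",
) -> ConnectivityMatrix:
    """Phase-locking-value matrix from analytic-signal instantaneous phases.

    The input is assumed band-limited already; no extra narrowband filtering
    is applied.  All-zero channels have undefined phase: their entries are
    set to 0 and logged.
    """
    data = np.asarray(data, dtype=float)
    dead = data.std(axis=1) == 0
    if dead.any():
        logger.warning("PLV: %d all-zero channel(s); entries set to 0", int(dead.sum()))
    phases = np.angle(signal.hilbert(data, axis=1))
    plv = plv_from_phases(phases)
    plv[dead, :] = 0.0
    plv[:, dead] = 0.0
    return ConnectivityMatrix(plv, "PLV", band, list(channels or []))


def coh_matrix(
    data: np.ndarray,
    fs: float,
    band_def: BandDefinition,
    params: SpectralParams | None = None,
    channels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Band-averaged magnitude-squared coherence matrix.

    MSC(f) = |S_xy|^2 / (S_xx S_yy) from Welch-averaged cross/auto spectra,
    then averaged over the frequency bins whose center lies in the band's
    half-open support.  Requires at least two averaging segments (a single
    segment gives MSC identically 1).
    """
    params = params or SpectralParams()
    data = np.asarray(data, dtype=float)
    n_ch, n_t = data.shape
    nperseg = params.nperseg(fs)
    if nperseg > n_t:
        raise ValueError(f"segment length {nperseg} exceeds epoch length {n_t}")
    noverlap = int(params.overlap * nperseg)
    step = nperseg - noverlap
    n_segments = 1 + (n_t - nperseg) // step
    if n_segments < 2:
        raise ValueError(
            f"coherence needs >= 2 averaging segments, got {n_segments} "
            f"(epoch {n_t} samples, segment {nperseg}, overlap {params.overlap})"
        )

    # one STFT pass per channel; Welch spectra are segment averages of these
    win = signal.get_window(params.window, nperseg)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    segs = np.lib.stride_tricks.sliding_window_view(data, nperseg, axis=1)[:, ::step, :]
    segs = segs - segs.mean(axis=2, keepdims=True)  # constant detrend per segment
    spec = np.fft.rfft(segs * win, axis=2)  # (n_ch, n_segments, n_freq)

    in_band = np.array([band_def.contains(f) for f in freqs])
    if not in_band.any():
        raise ValueError(
            f"no frequency bin inside band [{band_def.lo}, {band_def.hi}) "
            f"at resolution {fs / nperseg} Hz"
        )
    spec_b = spec[:, :, in_band]
    auto = np.mean(np.abs(spec_b) ** 2, axis=1)  # (n_ch, n_freq_band)
    dead = auto.sum(axis=1) == 0
    if dead.any():
        logger.warning("COH: %d zero-power channel(s) in band; entries set to 0", int(dead.sum()))

    out = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        if dead[i]:
            continue
        cross = np.mean(spec_b[i][None, :, :].conj() * spec_b[i + 1 :], axis=1)
        denom = auto[i][None, :] * auto[i + 1 :]
        with np.errstate(invalid="ignore", divide="ignore"):
            msc = np.where(denom > 0, np.abs(cross) ** 2 / denom, 0.0)
        vals = msc.mean(axis=1)
        vals[dead[i + 1 :]] = 0.0
        out[i, i + 1 :] = out[i + 1 :, i] = vals
    out = np.clip(out, 0.0, 1.0)
    return ConnectivityMatrix(out, "COH", band_def.name, list(channels or []))


def mean_strength(mat: ConnectivityMatrix) -> float:
    """Network strength V: mean of strictly positive upper-triangle entries."""
    iu = np.triu_indices(mat.n, k=1)
    vals = mat.values[iu]
    pos = vals[vals > 0]
    return float(pos.mean()) if pos.size else 0.0
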