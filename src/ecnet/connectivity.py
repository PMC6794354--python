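"""Band-wise effective connectivity via the phase slope index (PSI).

Pipeline: Welch-style segmentation with a Hanning taper (50% overlap,
frequency resolution df = fs/n_fft = 0.5 Hz by default) -> per-segment
cross-spectra S_ij(f) = X_i(f) conj(X_j(f)) -> pooled complex coherency
Coh_ij(f) = S_ij / sqrt(S_ii S_jj) -> raw PSI

    psi_raw_ij = Im( sum_{f in F} conj(Coh_ij(f)) Coh_ij(f + df) )

summed over the bin pairs (f, f+df) lying fully inside the half-open band
[lo, hi).  A fixed transmission delay tau produces a linear phase
Phi(f) = 2 pi f tau, so the sign of the slope gives the direction:
psi_ij > 0 means channel i sends to channel j.  Because the construction
uses only the imaginary part of coherency, instantaneous (zero-lag) mixing
of non-interacting sources contributes nothing in expectation.

The raw value is normalized by a jackknife standard deviation,
psi = psi_raw / sd_jk, giving an approximately unit-variance statistic;
|psi| > 2 then acts as a two-tailed 5% edge threshold.  The jackknife unit
is a disjoint *epoch* of adjacent segments (2 half-overlapped segments per
epoch by default): segments overlap only within an epoch, so the resampled
units are independent and the normalized statistic is calibrated.  The
thresholded matrix is a directed weighted adjacency (row sends to column);
skew-symmetry of psi means each significant pair contributes exactly one
directed edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .config import PipelineConfig
from .io import EEGRecording


@dataclass
class CrossSpectra:
    """Per-segment tapered spectra plus pooled cross-spectral matrix.

    Per-segment cross-spectral matrices are materialized on demand from the
    stored segment spectra (`segment_matrix`); the pooled mean S-bar over
    segments is kept explicitly.
    """

    seg_spectra: np.ndarray   # (n_segments, n_channels, n_freqs) complex
    freqs: np.ndarray         # (n_freqs,) Hz
    df: float                 # frequency resolution, Hz
    labels: tuple[str, ...]
    epochs: np.ndarray        # (n_segments,) epoch index per segment
    window: str = "hann"
    pooled: np.ndarray = field(init=False, repr=False)  # (n_freqs, C, C)

    def __post_init__(self) -> None:
        X = self.seg_spectra
        self.pooled = np.einsum("kcf,kdf->fcd", X, np.conj(X)) / X.shape[0]

    @property
    def n_segments(self) -> int:
        return self.seg_spectra.shape[0]

    @property
    def n_epochs(self) -> int:
        return len(np.unique(self.epochs))

    @property
    def n_channels(self) -> int:
        return self.seg_spectra.shape[1]

    def segment_matrix(self, k: int) -> np.ndarray:
        """Cross-spectral matrix of segment ``k``: (n_freqs, C, C), Hermitian."""
        X = self.seg_spectra[k]
        return np.einsum("cf,df->fcd", X, np.conj(X))


@dataclass
class PSIMatrix:
    psi_raw: np.ndarray       # (C, C) skew-symmetric, unnormalized
    jackknife_sd: np.ndarray  # (C, C) symmetric, >= 0
    psi: np.ndarray           # (C, C) normalized, skew-symmetric
    band: str
    freqs_used: np.ndarray    # bins f entering the slope sum
    labels: tuple[str, ...]


@dataclass
class Adjacency:
    """Thresholded directed weighted graph; ``matrix[i, j]`` is the weight of
    the edge i -> j (row sends to column)."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    band: str
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.count_nonzero(self.matrix))


def cross_spectra(rec: EEGRecording, df: float = 0.5, overlap: float = 0.5,
                  window: str = "hann", mask: np.ndarray | None = None,
                  epoch_segments: int = 2) -> CrossSpectra:
    """Epoch-structured segmented tapered spectra of all channels.

    Segment length is fs/df samples.  The recording is cut into disjoint
    epochs of ``epoch_segments`` overlapped segments each (segments never
    straddle an epoch boundary), so epochs are independent and can serve as
    jackknife units.  Epochs overlapping a True stretch of ``mask``
    (per-sample rejection mask) are dropped entirely.  Each segment is
    demeaned before tapering.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if epoch_segments < 1:
        raise ValueError("epoch_segments must be >= 1")
    nper = int(round(rec.fs / df))
    if nper < 2:
        raise ValueError("segment length below 2 samples")
    hop = max(1, int(round(nper * (1.0 - overlap))))
    ep_len = nper + (epoch_segments - 1) * hop
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
    starts: list[int] = []
    epochs: list[int] = []
    e_used = 0
    for e in range(rec.n_samples // ep_len):
        base = e * ep_len
        if mask is not None and mask[base:base + ep_len].any():
            continue
        starts.extend(base + k * hop for k in range(epoch_segments))
        epochs.extend([e_used] * epoch_segments)
        e_used += 1
    if e_used < 2:
        raise ValueError(
            f"only {e_used} usable epoch(s); need at least 2 for the "
            "jackknife")
    taper = _sig.get_window(window, nper)
    segs = np.stack([rec.data[:, s:s + nper] for s in starts])   # (k, C, nper)
    segs = segs - segs.mean(axis=2, keepdims=True)
    X = np.fft.rfft(segs * taper, axis=2)                        # (k, C, F)
    freqs = np.fft.rfftfreq(nper, d=1.0 / rec.fs)
    return CrossSpectra(seg_spectra=X, freqs=freqs, df=rec.fs / nper,
                        labels=rec.labels, epochs=np.asarray(epochs),
                        window=window)


def coherency(S: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Complex coherency from cross-spectral matrices (..., C, C).

    Bins with zero power on the diagonal yield NaN rows/columns; callers
    exclude those bins.
    """
    diag = np.real(np.einsum("...ii->...i", S))
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(diag[..., :, None] * diag[..., None, :]) + eps
        return S / denom


def pooled_coherency(cs: CrossSpectra) -> np.ndarray:
    """Coherency of the pooled (segment-averaged) cross-spectra: (F, C, C)."""
    return coherency(cs.pooled)


def _band_bins(freqs: np.ndarray, df: float, lo: float, hi: float) -> np.ndarray:
    """Indices of bins f such that both f and f + df lie inside [lo, hi)."""
    tol = 1e-9
    return np.flatnonzero((freqs >= lo - tol) & (freqs + df < hi - tol))


def psi(cs: CrossSpectra, band: tuple[float, float], band_name: str = "",
        ) -> PSIMatrix:
    """Jackknife-normalized PSI over a frequency band.

    The raw index is computed on the pooled coherency; the jackknife
    recomputes it with each epoch (disjoint group of segments) left out of
    the pool, and the (B-1)/B scaled standard deviation of those replicates
    normalizes the pooled value.
    """
    lo, hi = band
    idx = _band_bins(cs.freqs, cs.df, lo, hi)
    if idx.size < 1:
        raise ValueError(f"band ({lo}, {hi}) Hz contains no usable bin pair "
                         f"at df = {cs.df} Hz")
    ep_ids = np.unique(cs.epochs)
    B = len(ep_ids)
    if B < 2:
        raise ValueError("jackknife needs at least 2 epochs")
    need = np.concatenate([idx, [idx[-1] + 1]])
    X = cs.seg_spectra[:, :, need]                       # (k, C, B)
    S_seg = np.einsum("kcb,kdb->kbcd", X, np.conj(X))    # (k, B, C, C)
    # per-epoch sums of segment cross-spectra
    S_ep = np.stack([S_seg[cs.epochs == e].sum(axis=0) for e in ep_ids])
    counts = np.array([(cs.epochs == e).sum() for e in ep_ids])
    n = counts.sum()
    S_bar = S_ep.sum(axis=0) / n
    raw = _psi_band(S_bar)
    # leave-one-epoch-out pooled spectra, vectorized over epochs
    S_loo = (n * S_bar[None] - S_ep) / (n - counts)[:, None, None, None]
    reps = _psi_band(S_loo)                              # (B, C, C)
    sd = np.sqrt((B - 1) / B * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0))
    if np.all(sd == 0):
        raise ValueError("zero jackknife standard deviation (degenerate input)")
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(sd > 0, raw / np.where(sd > 0, sd, 1.0), 0.0)
    np.fill_diagonal(norm, 0.0)
    np.fill_diagonal(raw, 0.0)
    return PSIMatrix(psi_raw=raw, jackknife_sd=sd, psi=norm,
                     band=band_name or f"{lo}-{hi}Hz",
                     freqs_used=cs.freqs[idx], labels=cs.labels)


def _psi_band(S: np.ndarray) -> np.ndarray:
    """Raw PSI from pooled cross-spectra over contiguous band bins.

    ``S`` has shape (..., B, C, C) where the B bins are f_1 .. f_B with the
    last one serving only as the f + df partner of f_{B-1}.
    """
    coh = coherency(S)
    prod = np.conj(coh[..., :-1, :, :]) * coh[..., 1:, :, :]
    return np.imag(prod.sum(axis=-3))


def threshold_adjacency(psim: PSIMatrix, threshold: float = 2.0) -> Adjacency:
    """Keep entries with psi > threshold at their original value.

    Skew-symmetry of psi guarantees at most one direction per pair survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    A = np.where(psim.psi > threshold, psim.psi, 0.0)
    np.fill_diagonal(A, 0.0)
    return Adjacency(matrix=A, labels=psim.labels, band=psim.band,
                     threshold=threshold)


def psi_all_bands(rec: EEGRecording, config: PipelineConfig | None = None,
                  mask: np.ndarray | None = None,
                  bands: dict[str, tuple[float, float]] | None = None,
                  ) -> dict[str, Adjacency]:
    """Thresholded adjacency per frequency band (cross-spectra computed once).

    Each returned Adjacency carries its PSIMatrix as the ``psi`` attribute.
    """
    cfg = config or PipelineConfig()
    bands = bands if bands is not None else cfg.bands
    cs = cross_spectra(rec, df=cfg.df, overlap=cfg.overlap, mask=mask)
    out: dict[str, Adjacency] = {}
    for name, (lo, hi) in bands.items():
        pm = psi(cs, (lo, hi), band_name=name)
        adj = threshold_adjacency(pm, cfg.psi_threshold)
        adj.psi = pm  # attach for downstream hemisphere-flow analysis
        out[name] = adj
    return out
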