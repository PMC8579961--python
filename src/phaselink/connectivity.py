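"""Band-limited cross-spectra and phase-lag-index connectivity.

The weighted phase lag index (WPLI) of a channel pair weighs the sign of each
epoch's imaginary cross-spectrum by its magnitude,

    WPLI = |sum_t Im(S_t)| / sum_t |Im(S_t)|,

and is insensitive to instantaneous (zero-lag, volume-conducted) coupling,
which contributes no imaginary cross-spectral energy.  The debiased estimator
of *squared* WPLI removes the positive sample bias of WPLI^2 by using only
cross-epoch products (a U-statistic over epoch pairs j != k):

    DWPLI = ((sum_t a_t)^2 - sum_t a_t^2) / ((sum_t |a_t|)^2 - sum_t a_t^2),

with a_t = Im(S_t).  DWPLI may be negative and is deliberately not clipped:
clipping would bias group averages upward.

Cross-spectra are estimated per epoch with a Hann-tapered FFT and collapsed
over the FFT bins inside the band before the epoch-wise estimator (the
per-bin alternative is available via ``band_collapse="epochs_per_bin"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import BandSpec, EpochedRecording, ROIScheme

__all__ = [
    "CrossSpectra",
    "ConnectivityMatrix",
    "RegionalConnectivity",
    "bandpass_epochs",
    "cross_spectra",
    "wpli",
    "dwpli",
    "band_connectivity",
    "regional_mean",
]

logger = logging.getLogger(__name__)


@dataclass
class CrossSpectra:
    """Band-collapsed cross-spectral densities, one complex value per
    (channel pair, epoch).

    ``values[p, t]`` is the cross-spectral density of upper-triangle pair
    ``p`` (ordered as ``numpy.triu_indices``) in epoch ``t``, averaged over
    the FFT bins inside ``band``.
    """

    values: np.ndarray  # complex, (n_pairs, n_epochs)
    channel_labels: tuple[str, ...]
    band: BandSpec

    @property
    def n_epochs(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def pair_index(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_channels, k=1)


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel connectivity with zero diagonal."""

    W: np.ndarray
    channel_labels: tuple[str, ...]
    estimator: str
    band: BandSpec

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be square, got {W.shape}")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        np.fill_diagonal(W, 0.0)
        self.W = W

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_channels, k=1)
        return self.W[iu]

    def global_mean(self) -> float:
        """Mean over all distinct channel pairs."""
        return float(self.upper_values().mean())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.W, index=self.channel_labels, columns=self.channel_labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, estimator: str, band: BandSpec) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), tuple(df.columns), estimator, band)


@dataclass
class RegionalConnectivity:
    """Region-pair means of a connectivity matrix plus the global mean."""

    table: pd.DataFrame  # columns: region_a, region_b, value
    global_mean: float

    def value(self, a: str, b: str) -> float:
        t = self.table
        m = ((t.region_a == a) & (t.region_b == b)) | ((t.region_a == b) & (t.region_b == a))
        if not m.any():
            raise KeyError(f"no region pair ({a}, {b})")
        return float(t.loc[m, "value"].iloc[0])


def bandpass_epochs(rec: EpochedRecording, band: BandSpec, order: int = 4) -> EpochedRecording:
    """Zero-phase Butterworth band-pass of every epoch.

    Each epoch is filtered independently with ``sosfiltfilt`` (forward and
    backward pass, so the effective attenuation is twice the filter order);
    edges are handled by scipy's default odd-symmetric padding.
    """
    band.validate_for(rec.fs)
    sos = signal.butter(order, [band.f_lo, band.f_hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return EpochedRecording(filtered, rec.fs, rec.channel_labels, rec.epoch_length_s)


def _band_bins(n_samples: int, fs: float, band: BandSpec) -> np.ndarray:
    # half-open [f_lo, f_hi): adjacent bands (e.g. delta 1-4, theta 4-7 Hz)
    # must not share the boundary bin
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    bins = np.nonzero((freqs >= band.f_lo) & (freqs < band.f_hi))[0]
    if bins.size == 0:
        raise ValueError(
            f"band {band.name!r} ({band.f_lo}-{band.f_hi} Hz) contains no FFT bin "
            f"at {n_samples} samples/epoch; use longer epochs"
        )
    return bins


def _tapered_fft(rec: EpochedRecording, band: BandSpec) -> np.ndarray:
    """Hann-tapered rFFT of every (channel, epoch), restricted to in-band bins."""
    band.validate_for(rec.fs)
    taper = signal.windows.hann(rec.n_samples, sym=False)
    bins = _band_bins(rec.n_samples, rec.fs, band)
    spectra = np.fft.rfft(rec.data * taper, axis=-1)
    return spectra[..., bins]  # (channel, epoch, bin)


def cross_spectra(rec: EpochedRecording, band: BandSpec) -> CrossSpectra:
    """Per-epoch cross-spectral density for every channel pair, collapsed
    over the FFT bins inside ``band``."""
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if rec.n_epochs < 2:
        raise ValueError("need at least 2 epochs for epoch-wise estimation")
    X = _tapered_fft(rec, band)  # (ch, ep, bin)
    # S_xy[e] = mean_b X[x,e,b] * conj(X[y,e,b])
    S = np.einsum("aeb,ceb->ace", X, np.conj(X)) / X.shape[-1]
    iu = np.triu_indices(rec.n_channels, k=1)
    return CrossSpectra(S[iu], rec.channel_labels, band)


def _pairs_to_matrix(pair_values: np.ndarray, n: int) -> np.ndarray:
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    W[iu] = pair_values
    return W + W.T


def _wpli_from_imag(a: np.ndarray) -> np.ndarray:
    """WPLI per pair from imaginary parts a of shape (..., n_epochs)."""
    num = np.abs(a.sum(axis=-1))
    den = np.abs(a).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def _dwpli_from_imag(a: np.ndarray) -> np.ndarray:
    """Debiased squared-WPLI per pair from imaginary parts (..., n_epochs)."""
    s = a.sum(axis=-1)
    ssq = (a**2).sum(axis=-1)
    sabs = np.abs(a).sum(axis=-1)
    num = s**2 - ssq
    den = sabs**2 - ssq
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def wpli(cs: CrossSpectra) -> ConnectivityMatrix:
    """Weighted phase lag index per channel pair; values in [0, 1].

    Pairs with no imaginary cross-spectral energy (zero denominator) return 0
    by convention — no detectable lagged coupling — and are counted in a QC
    log message.
    """
    a = np.imag(cs.values)
    vals = _wpli_from_imag(a)
    _log_zero_denominator(np.abs(a).sum(axis=-1), "wpli")
    return ConnectivityMatrix(
        _pairs_to_matrix(vals, cs.n_channels), cs.channel_labels, "wpli", cs.band
    )


def dwpli(cs: CrossSpectra) -> ConnectivityMatrix:
    """Debiased squared-WPLI per channel pair; values in [-1, 1], not clipped."""
    if cs.n_epochs < 2:
        raise ValueError("debiased estimation requires at least 2 epochs")
    a = np.imag(cs.values)
    vals = _dwpli_from_imag(a)
    _log_zero_denominator(np.abs(a).sum(axis=-1) ** 2 - (a**2).sum(axis=-1), "dwpli")
    return ConnectivityMatrix(
        _pairs_to_matrix(vals, cs.n_channels), cs.channel_labels, "dwpli", cs.band
    )


def _log_zero_denominator(den: np.ndarray, name: str) -> None:
    n_zero = int((den <= 0).sum())
    if n_zero:
        logger.info("%s: %d pair(s) with zero denominator set to 0", name, n_zero)


def band_connectivity(
    rec: EpochedRecording,
    band: BandSpec,
    estimator: str = "dwpli",
    band_collapse: str = "bins_then_epochs",
) -> ConnectivityMatrix:
    """One-call band-limited connectivity matrix for a recording.

    ``bins_then_epochs`` (default) averages the cross-spectral density over
    in-band FFT bins before the epoch-wise estimator; ``epochs_per_bin`` runs
    the estimator per bin and averages the per-bin values afterwards.
    """
    if estimator not in ("wpli", "dwpli"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if band_collapse == "bins_then_epochs":
        cs = cross_spectra(rec, band)
        return wpli(cs) if estimator == "wpli" else dwpli(cs)
    if band_collapse != "epochs_per_bin":
        raise ValueError(f"unknown band_collapse {band_collapse!r}")
    if rec.n_epochs < 2:
        raise ValueError("need at least 2 epochs")
    X = _tapered_fft(rec, band)  # (ch, ep, bin)
    iu = np.triu_indices(rec.n_channels, k=1)
    S = np.einsum("aeb,ceb->aceb", X, np.conj(X))[iu]  # (pair, ep, bin)
    a = np.imag(S).transpose(0, 2, 1)  # (pair, bin, ep)
    fn = _wpli_from_imag if estimator == "wpli" else _dwpli_from_imag
    vals = fn(a).mean(axis=-1)
    return ConnectivityMatrix(
        _pairs_to_matrix(vals, rec.n_channels), rec.channel_labels, estimator, band
    )


def regional_mean(W: ConnectivityMatrix, roi: ROIScheme) -> RegionalConnectivity:
    """Average connectivity over region pairs (and within regions).

    For an unordered region pair (A, B), the mean runs over all electrode
    pairs (a in A, b in B) with a != b; for A == B that is all distinct
    electrode pairs within the region.  ``global_mean`` is the mean over all
    distinct channel pairs of the full matrix.
    """
    roi.validate_against(W.channel_labels)
    index = {lab: i for i, lab in enumerate(W.channel_labels)}
    names = roi.names
    rows = []
    for ai, a in enumerate(names):
        for b in names[ai:]:
            ia = [index[ch] for ch in roi.regions[a]]
            ib = [index[ch] for ch in roi.regions[b]]
            vals = [W.W[i, j] for i in ia for j in ib if i != j]
            if a == b:
                # each unordered within-region pair counted once
                vals = [W.W[i, j] for k, i in enumerate(ia) for j in ia[k + 1 :]]
            rows.append({"region_a": a, "region_b": b, "value": float(np.mean(vals))})
    return RegionalConnectivity(pd.DataFrame(rows), W.global_mean())
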