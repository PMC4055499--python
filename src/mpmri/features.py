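"""Quantitative fcMRI features: seed connectivity summaries, VMHC, fALFF.

Operating on region-level time series, the voxel-count feature of a seed
connectivity map becomes a suprathreshold REGION count: N is the number of
regions whose standardized Fisher z exceeds the conventional 2.3 threshold
(positive tail only) and Z is the mean z over those regions. Fisher z is
standardized by sqrt(T - 3) so the threshold keeps its one-sided normal
interpretation. VMHC applies the same summary to homotopic left/right pair
correlations. fALFF is the fraction of spectral amplitude falling in the
low-frequency band (0.01-0.08 Hz by default).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_Z_THRESHOLD = 2.3
FALFF_BAND = (0.01, 0.08)  # Hz

_R_CLIP = 1.0 - 1e-12


@dataclass
class SeedSummary:
    """Suprathreshold count (N) and mean Fisher z (Z) of a connectivity map."""

    seed_name: str
    n_suprathreshold: int
    mean_z: float
    z_threshold: float = DEFAULT_Z_THRESHOLD
    empty: bool = False   # True when no region exceeded the threshold


@dataclass
class FalffResult:
    values: np.ndarray          # per-region fractional amplitude in [0, 1]
    band_low: float = FALFF_BAND[0]
    band_high: float = FALFF_BAND[1]


def _nyquist(tr: float) -> float:
    return 1.0 / (2.0 * tr)


def bandpass_filter(ts: np.ndarray, low: float, high: float, tr: float) -> np.ndarray:
    """Frequency-domain mask retaining bins in [low, high] Hz."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if not 0 <= low < high <= _nyquist(tr) + 1e-12:
        raise ValueError(f"band [{low}, {high}] Hz outside [0, Nyquist={_nyquist(tr)}]")
    n = ts.shape[-1]
    spec = np.fft.rfft(ts, axis=-1)
    freqs = np.fft.rfftfreq(n, d=tr)
    spec[:, (freqs < low) | (freqs > high)] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def fisher_z(r: np.ndarray | float, n_timepoints: int) -> np.ndarray:
    """Standardized Fisher transform: atanh(r) * sqrt(T - 3), r clipped."""
    r = np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP)
    return np.arctanh(r) * np.sqrt(n_timepoints - 3)


def seed_connectivity_map(ts: np.ndarray, seed: "set[int] | list[int]") -> pd.Series:
    """Standardized Fisher-z of each non-seed region against the seed mean.

    The seed reference is the mean time course over the (bilateral) seed
    regions; seed regions are excluded from the returned map, which is
    indexed by region index.
    """
    ts = np.asarray(ts, dtype=float)
    seed = sorted(set(int(i) for i in seed))
    if not seed:
        raise ValueError("seed region set is empty")
    ref = ts[seed].mean(axis=0)
    if ref.std() == 0:
        raise ValueError("seed reference time course is constant")
    others = [i for i in range(ts.shape[0]) if i not in set(seed)]
    refc = ref - ref.mean()
    x = ts[others] - ts[others].mean(axis=1, keepdims=True)
    denom = np.linalg.norm(x, axis=1) * np.linalg.norm(refc)
    if np.any(denom == 0):
        bad = others[int(np.nonzero(denom == 0)[0][0])]
        raise ValueError(f"constant time series for region {bad}")
    r = (x @ refc) / denom
    return pd.Series(fisher_z(r, ts.shape[1]), index=others, name="z")


def summarize_seed_map(zmap: "pd.Series | np.ndarray", z_threshold: float = DEFAULT_Z_THRESHOLD,
                       seed_name: str = "") -> SeedSummary:
    """N = #{z > threshold} (strict), Z = their mean (0, flagged, if N = 0)."""
    if z_threshold <= 0:
        raise ValueError("z threshold must be positive")
    z = np.asarray(zmap, dtype=float)
    supra = z[z > z_threshold]
    if supra.size == 0:
        return SeedSummary(seed_name, 0, 0.0, z_threshold, empty=True)
    return SeedSummary(seed_name, int(supra.size), float(supra.mean()), z_threshold)


def vmhc(ts: np.ndarray, pairs: "list[tuple[int, int]]",
         z_threshold: float = DEFAULT_Z_THRESHOLD) -> SeedSummary:
    """Homotopic connectivity: per-pair correlation -> Fisher z -> N and Z."""
    if not pairs:
        raise ValueError("no homotopic pairs given")
    ts = np.asarray(ts, dtype=float)
    zs = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        xa, xb = ts[a], ts[b]
        if xa.std() == 0 or xb.std() == 0:
            bad = a if xa.std() == 0 else b
            raise ValueError(f"constant time series for region {bad} in pair {k}")
        r = float(np.corrcoef(xa, xb)[0, 1])
        zs[k] = fisher_z(r, ts.shape[1])
    return summarize_seed_map(zs, z_threshold, seed_name="vmhc")


def falff(ts: np.ndarray, band_low: float = FALFF_BAND[0],
          band_high: float = FALFF_BAND[1], tr: float = 2.0) -> FalffResult:
    """Fractional amplitude of low-frequency fluctuations per region.

    Amplitude is |FFT| of the demeaned series; the result is the band
    amplitude divided by the total over all positive-frequency bins.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n = ts.shape[-1]
    if n < 8:
        raise ValueError("need at least 8 timepoints for fALFF")
    if not 0 <= band_low < band_high <= _nyquist(tr) + 1e-12:
        raise ValueError(f"band [{band_low}, {band_high}] Hz outside Nyquist range")
    demeaned = ts - ts.mean(axis=-1, keepdims=True)
    amp = np.abs(np.fft.rfft(demeaned, axis=-1))[:, 1:]   # drop DC
    freqs = np.fft.rfftfreq(n, d=tr)[1:]
    total = amp.sum(axis=-1)
    if np.any(total == 0):
        bad = int(np.nonzero(total == 0)[0][0])
        raise ValueError(f"constant time series for region {bad}")
    in_band = (freqs >= band_low) & (freqs <= band_high)
    vals = amp[:, in_band].sum(axis=-1) / total
    return FalffResult(values=vals, band_low=band_low, band_high=band_high)
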