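"""Band filtering, Welch power spectral density, and the Asym statistic.

The asymmetry of a (right, left) channel pair in a band is the mean over
in-band frequency bins of the natural-log ratio of the two channels'
power densities:

    Asym_band(ch1, ch2) = mean_f [ ln P_ch1(f) - ln P_ch2(f) ],  f in band

computed on the 10 s epoch ending at each SWB report. By default the epoch
is band-pass filtered (zero-phase 4th-order Butterworth) before the PSD is
estimated; because Asym is a ratio, any gain shared by both channels - filter
roll-off at the band edges included - cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import (
    QUADRANTS,
    AsymSample,
    BandDef,
    ConfigurationError,
    DegenerateDataError,
    Epoch,
    get_band,
    logger,
)

#: Fraction of Nyquist used as the hard upper edge for filter design; the
#: nominal 100 Hz upper bound of gamma/non is unreachable at fs = 128.
NYQUIST_MARGIN = 0.95

DEFAULT_SEG_LEN = 256      # 2 s at 128 Hz -> 0.5 Hz resolution
DEFAULT_OVERLAP = 0.5


def clip_band(band: str | BandDef, fs: float) -> tuple[float, float]:
    """Clip band edges to [0.5 Hz, 0.95 x Nyquist]; error if nothing remains."""
    band = get_band(band)
    lo = max(band.f_low, 0.5)
    hi = min(band.f_high, NYQUIST_MARGIN * fs / 2.0)
    if lo >= hi:
        raise ConfigurationError(
            f"band {band.name} [{band.f_low}, {band.f_high}] Hz is empty "
            f"after clipping to [0.5, {NYQUIST_MARGIN * fs / 2.0:g}] at fs={fs:g}"
        )
    return lo, hi


def bandpass(
    x: np.ndarray, band: str | BandDef, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    lo, hi = clip_band(band, fs)
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, float), axis=-1)


@dataclass(frozen=True)
class PSD:
    """One-sided Welch power spectral density, uniform grid 0..Nyquist.

    ``density`` has frequency on the last axis, in uV^2/Hz; its integral
    over frequency approximates the signal variance (Parseval).
    """

    frequencies: np.ndarray
    density: np.ndarray


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_len: int = DEFAULT_SEG_LEN,
    overlap: float = DEFAULT_OVERLAP,
) -> PSD:
    """Welch PSD: mean over 50%-overlapping Hanning-windowed periodograms."""
    x = np.asarray(x, float)
    if x.shape[-1] < seg_len:
        raise ConfigurationError(
            f"signal length {x.shape[-1]} < required minimum seg_len={seg_len}"
        )
    freqs, dens = sps.welch(
        x, fs=fs, window="hann", nperseg=seg_len,
        noverlap=int(round(seg_len * overlap)), detrend="constant",
        scaling="density", axis=-1,
    )
    return PSD(frequencies=freqs, density=dens)


def band_bin_mask(freqs: np.ndarray, band: str | BandDef, fs: float) -> np.ndarray:
    """Boolean mask of PSD bins inside the (clipped) band, edges included."""
    lo, hi = clip_band(band, fs)
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


def band_density(
    x: np.ndarray,
    fs: float,
    band: str | BandDef,
    prefilter: bool = True,
    seg_len: int = DEFAULT_SEG_LEN,
    overlap: float = DEFAULT_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """In-band PSD of ``x`` (any leading shape, samples on the last axis).

    Returns (in-band frequencies, density restricted to the band). With
    ``prefilter`` the signal is Butterworth band-passed before estimation;
    otherwise the bins of the broadband PSD are selected directly.
    """
    if prefilter:
        x = bandpass(x, band, fs)
    psd = welch_psd(x, fs, seg_len=seg_len, overlap=overlap)
    mask = band_bin_mask(psd.frequencies, band, fs)
    return psd.frequencies[mask], psd.density[..., mask]


def pair_log_ratio_mean(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Mean over bins of ln(d1/d2), skipping bins where either density is 0.

    ``d1``/``d2`` have bins on the last axis; returns an array without that
    axis, NaN where no valid bin remains.
    """
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    valid = (d1 > 0) & (d2 > 0)
    n_valid = valid.sum(axis=-1)
    if np.any(~valid & (n_valid[..., None] > 0)):
        logger.debug("pair_log_ratio_mean: zero-density bins excluded from mean")
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = np.where(valid, np.log(d1, where=d1 > 0, out=np.zeros_like(d1))
                        - np.log(d2, where=d2 > 0, out=np.zeros_like(d2)), 0.0)
    with np.errstate(invalid="ignore"):
        out = diff.sum(axis=-1) / n_valid
    return np.where(n_valid > 0, out, np.nan)


def quadrant_signal(epoch: Epoch, quadrant: str) -> np.ndarray:
    """Sample-wise mean of the quadrant's member channels that are not bad."""
    if quadrant not in QUADRANTS:
        raise ConfigurationError(
            f"unknown quadrant {quadrant!r}; known: {sorted(QUADRANTS)}"
        )
    rec = epoch.recording
    members = [
        ch for ch in QUADRANTS[quadrant]
        if ch in rec.channel_labels and ch not in rec.bad_channels
    ]
    if not members:
        raise DegenerateDataError(
            f"all members of quadrant {quadrant} are bad or absent"
        )
    idx = [rec.index_of(ch) for ch in members]
    return epoch.samples[idx].mean(axis=0)


def _epoch_signal(epoch: Epoch, name: str) -> np.ndarray:
    """Channel or quadrant signal for the asymmetry computation."""
    if name in QUADRANTS:
        return quadrant_signal(epoch, name)
    rec = epoch.recording
    if name in rec.bad_channels:
        raise DegenerateDataError(f"channel {name} is flagged bad")
    return epoch.samples[rec.index_of(name)]


def asym(
    epoch: Epoch,
    ch1: str,
    ch2: str,
    band: str | BandDef,
    prefilter: bool = True,
    seg_len: int = DEFAULT_SEG_LEN,
    overlap: float = DEFAULT_OVERLAP,
    epoch_index: int = -1,
) -> AsymSample:
    """Asym statistic of a (right, left) channel-or-quadrant pair on one epoch."""
    if ch1 == ch2:
        raise ConfigurationError("ch1 and ch2 must differ")
    band = get_band(band)
    pair = np.stack([_epoch_signal(epoch, ch1), _epoch_signal(epoch, ch2)])
    _, dens = band_density(
        pair, epoch.fs, band, prefilter=prefilter, seg_len=seg_len, overlap=overlap
    )
    value = float(pair_log_ratio_mean(dens[0], dens[1]))
    if np.isnan(value):
        raise DegenerateDataError(
            f"all-zero band power in band {band.name} for pair ({ch1}, {ch2})"
        )
    rec = epoch.recording
    return AsymSample(
        band=band.name, ch1=ch1, ch2=ch2, value=value, swb=epoch.swb,
        participant_id=rec.participant_id, run_id=rec.run_id,
        epoch_index=epoch_index,
    )


def asym_table(samples: list[AsymSample], reference: str = "original"):
    """Long-format table of asymmetry samples (one row per epoch and pair)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id, "run_id": s.run_id,
                "epoch_index": s.epoch_index, "reference": reference,
                "band": s.band, "ch1": s.ch1, "ch2": s.ch2,
                "asym": s.value, "swb": s.swb,
            }
            for s in samples
        ]
    )
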