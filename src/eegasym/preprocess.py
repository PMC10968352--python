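"""Minimal preprocessing: detrending, probability-based bad-channel
detection (two passes), posterior re-referencing, and epoch extraction.

The bad-channel criterion follows the "probability" idea: each channel is
robustly standardized (median/MAD) and summarized by the negative mean
log-likelihood of its samples under a kernel density estimate of the pooled
standardized amplitude distribution of all surviving channels; channels
whose measure is a z-score outlier across channels are flagged. The
criterion is deliberately invariant to a channel's static gain: a pure gain
multiplies the band power density uniformly, which only shifts the
log-power-ratio asymmetry by a constant and cannot bias its slope on the
well-being rating. What the criterion targets is distribution shape -
impulsive spikes, clipping, bimodality. (Evaluating each channel under its
own density instead would let the fit explain away its own outliers,
leaving sparse spikes undetectable.) Zero-variance channels are always
flagged. Artifact-component
removal (wavelet-ICA / automated component classification) is intentionally
not reimplemented here; ``run_analysis`` exposes a ``cleaner`` hook where an
external cleaning step can be inserted, and the synthetic generator produces
artifact-free data.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import (
    POSTERIOR_SET,
    ConfigurationError,
    DegenerateDataError,
    Epoch,
    Recording,
    SWBReport,
    logger,
)

MIN_SURVIVORS = 4


def detrend(rec: Recording) -> Recording:
    """Remove each channel's least-squares straight line (intercept + slope*t).

    Idempotent; output channels have zero mean and zero linear trend to
    float tolerance.
    """
    out = rec.copy()
    x = out.samples
    n = x.shape[1]
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:  # single-sample recording: just remove the mean
        out.samples = x - x.mean(axis=1, keepdims=True)
        return out
    slope = (x @ tc) / denom
    out.samples = x - x.mean(axis=1, keepdims=True) - slope[:, None] * tc
    return out


_DENSITY_FLOOR = 1e-12


def _subsample(x: np.ndarray, max_samples: int) -> np.ndarray:
    if x.size <= max_samples:
        return x
    step = x.size / max_samples
    return x[np.round(np.arange(max_samples) * step).astype(int)]


def _standardize(x: np.ndarray) -> np.ndarray:
    """Center and scale robustly (median / 1.4826*MAD) so the probability
    measure sees distribution shape, not gain."""
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    if mad == 0.0:
        sd = x.std()
        mad = sd if sd > 0 else 1.0
    return (x - med) / mad


def _loo_kde_nll(channels: list[np.ndarray]) -> np.ndarray:
    """Leave-one-out pooled-KDE negative mean log-likelihood per channel.

    All channels share one regular grid; each channel's histogram is
    smoothed with a Gaussian of Silverman-rule bandwidth (robust pooled
    scale, so a single wild channel does not wash it out), and channel i is
    evaluated under the pooled density of the other channels. Leaving the
    channel out keeps its own outliers from explaining themselves.
    """
    pooled = np.concatenate(channels)
    sd = float(np.std(pooled))
    iqr = float(np.subtract(*np.percentile(pooled, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * scale * pooled.size ** (-0.2)
    lo, hi = pooled.min() - 3 * bw, pooled.max() + 3 * bw
    grid_size = int(np.clip(np.ceil(2 * (hi - lo) / bw), 256, 8192))
    edges = np.linspace(lo, hi, grid_size + 1)
    binw = edges[1] - edges[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = np.stack([
        gaussian_filter1d(
            np.histogram(x, bins=edges)[0].astype(float),
            sigma=bw / binw, mode="constant",
        ) / (x.size * binw)
        for x in channels
    ])
    total = dens.sum(axis=0)
    nll = np.empty(len(channels))
    for i, x in enumerate(channels):
        loo = (total - dens[i]) / (len(channels) - 1)
        at_x = np.interp(x, centers, loo)
        nll[i] = -np.mean(np.log(np.maximum(at_x, _DENSITY_FLOOR)))
    return nll


def detect_bad_channels(
    rec: Recording,
    z_thresh: float = 3.0,
    n_iter: int = 2,
    max_samples: int = 2048,
) -> set[str]:
    """Flag channels whose amplitude-distribution likelihood is an outlier.

    Zero-variance channels are always flagged. Then, per iteration, each
    surviving channel is robustly standardized and its negative mean
    log-likelihood under the leave-one-out pooled kernel density of the
    other surviving standardized channels is z-scored across channels;
    channels with ``|z| > z_thresh`` are flagged and the detector repeats
    on the survivors ``n_iter`` times (two passes by default). Stops early
    with a warning if fewer than four channels would survive. The measure
    is gain-invariant by construction (see module docstring).
    """
    survivors = [ch for ch in rec.channel_labels if ch not in rec.bad_channels]
    if len(survivors) < MIN_SURVIVORS:
        raise ConfigurationError(
            f"need >= {MIN_SURVIVORS} unflagged channels, have {len(survivors)}"
        )
    flagged: set[str] = set()
    variances = rec.samples.var(axis=1)
    for ch in list(survivors):
        if variances[rec.index_of(ch)] == 0.0:
            flagged.add(ch)
            survivors.remove(ch)

    for _ in range(n_iter):
        if len(survivors) < MIN_SURVIVORS:
            logger.warning(
                "bad-channel detection stopped early: only %d channels left",
                len(survivors),
            )
            break
        subs = [
            _standardize(_subsample(rec.samples[rec.index_of(ch)], max_samples))
            for ch in survivors
        ]
        nll = _loo_kde_nll(subs)
        sd = nll.std(ddof=1)
        if sd == 0.0:
            break
        z = (nll - nll.mean()) / sd
        new = [ch for ch, zi in zip(survivors, z) if abs(zi) > z_thresh]
        if not new:
            break
        flagged.update(new)
        survivors = [ch for ch in survivors if ch not in new]
    return flagged


def rereference(
    rec: Recording,
    new_ref: str,
    subset: tuple[str, ...] | None = None,
) -> Recording:
    """Subtract ``new_ref``'s signal from the ``subset`` channels.

    The default subset is the posterior sensor set (T7, P7, O1, O2, P8, T8).
    Channels outside the subset are unchanged. Not idempotent: applying it
    twice subtracts the reference twice. Re-referencing to a channel flagged
    bad is invalid.
    """
    if subset is None:
        subset = POSTERIOR_SET
    if new_ref not in rec.channel_labels:
        raise ConfigurationError(f"reference channel {new_ref!r} not in recording")
    if new_ref in subset:
        raise ConfigurationError(f"reference {new_ref!r} may not be in the subset")
    if new_ref in rec.bad_channels:
        raise DegenerateDataError(
            f"cannot re-reference to bad channel {new_ref!r} "
            f"({rec.participant_id}/{rec.run_id})"
        )
    out = rec.copy()
    ref_sig = out.samples[out.index_of(new_ref)].copy()
    for ch in subset:
        if ch in out.channel_labels:
            out.samples[out.index_of(ch)] -= ref_sig
    out.reference = new_ref
    return out


def extract_epochs(
    rec: Recording,
    reports: list[SWBReport],
    duration: float = 10.0,
) -> list[Epoch]:
    """One epoch per report over the half-open window [t - duration, t).

    Sample indices are [round((t - duration) * fs), round(t * fs)). Reports
    whose window does not fit inside the run are skipped with a warning
    (no zero-padding, which would bias the PSD).
    """
    epochs = []
    for rep in reports:
        i1 = int(round(rep.time_s * rec.fs))
        i0 = int(round((rep.time_s - duration) * rec.fs))
        if i0 < 0 or i1 > rec.n_samples:
            logger.warning(
                "%s/%s: report at t=%.1f s has no full %g s window; skipped",
                rec.participant_id, rec.run_id, rep.time_s, duration,
            )
            continue
        epochs.append(
            Epoch(
                recording=rec,
                swb=rep.swb,
                t_start=rep.time_s - duration,
                t_end=rep.time_s,
                samples=rec.samples[:, i0:i1],
            )
        )
    return epochs
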