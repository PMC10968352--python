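"""Group inference: per-participant SWB filtering, SMOTE balancing,
repeated regression with averaged slopes, one-sample slope t-test with
95% CI, and Benjamini-Yekutieli FDR control.

The rating distribution is imbalanced (most epochs carry ratings 6-8), so a
plain regression would overfit the frequent ratings. Each participant's
(Asym, SWB) samples are therefore balanced with SMOTE - synthetic minority
samples interpolated between same-class nearest neighbours in the 1-D Asym
feature space - before an ordinary least-squares fit. Because SMOTE is
stochastic, the balance-and-fit step is repeated (10 times by default) and
the slopes and intercepts averaged. Group inference is a two-sided
one-sample t-test of the participant mean slopes against zero; the many
(pair, band) tests of one family are corrected with the Benjamini-Yekutieli
step-up procedure, which is valid under arbitrary dependence.

SMOTE is reimplemented here (1-D feature, seed-controlled) so its behaviour
is fully specified; BY correction is delegated to statsmodels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .core import AsymSample, ConfigurationError, DegenerateDataError, logger

MIN_CLASS_COUNT = 3       # ratings reported fewer times are dropped
MIN_DISTINCT_SWB = 3      # participants with fewer distinct ratings are excluded


@dataclass
class ParticipantFit:
    """Mean slope/intercept over the SMOTE-balanced repeat fits."""

    participant_id: str
    slope: float
    intercept: float
    n_repeats: int
    n_samples_used: int


@dataclass
class GroupResult:
    """One hypothesis-test row: group slope t-test plus BY-adjusted p."""

    ch1: str
    ch2: str
    band: str
    reference: str
    n_participants: int
    mean_slope: float
    t_stat: float
    p_value: float
    ci_low: float
    ci_high: float
    p_adjusted: float = np.nan
    significant: bool = False


def filter_swb_arrays(
    values: np.ndarray, swb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Array form of the per-participant SWB filter.

    Drops all samples whose rating occurs fewer than MIN_CLASS_COUNT times;
    the participant is excluded if fewer than MIN_DISTINCT_SWB distinct
    ratings remain.
    """
    values = np.asarray(values, float)
    swb = np.asarray(swb, int)
    counts = Counter(swb.tolist())
    keep_ratings = {r for r, c in counts.items() if c >= MIN_CLASS_COUNT}
    mask = np.isin(swb, sorted(keep_ratings))
    excluded = len(keep_ratings) < MIN_DISTINCT_SWB
    return values[mask], swb[mask], excluded


def filter_participant_swb(
    samples: list[AsymSample],
) -> tuple[list[AsymSample], bool]:
    """Drop under-reported ratings; flag the participant if < 3 distinct remain."""
    swb = np.array([s.swb for s in samples], int)
    counts = Counter(swb.tolist())
    keep = {r for r, c in counts.items() if c >= MIN_CLASS_COUNT}
    kept = [s for s in samples if s.swb in keep]
    return kept, len(keep) < MIN_DISTINCT_SWB


def smote_balance(
    values: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every rating class to the majority count by interpolation.

    Repeatedly: pick a random class sample x, pick a random one of its
    k nearest same-class neighbours x' (k auto-reduced to class size - 1),
    emit x + u*(x' - x) with u ~ Uniform(0, 1). Originals are always
    retained, so synthetics lie within the class's [min, max]. Bit
    reproducible given the seed; class counts depend only on the input.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ConfigurationError("values and labels must be 1-D and aligned")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    classes = sorted(set(labels.tolist()))
    counts = {c: int(np.sum(labels == c)) for c in classes}
    n_max = max(counts.values())
    out_v = [values]
    out_l = [labels]
    for c in classes:
        need = n_max - counts[c]
        if need == 0:
            continue
        if counts[c] < 2:
            raise DegenerateDataError(
                f"class {c} has {counts[c]} sample(s); interpolation impossible"
            )
        v = values[labels == c]
        k = min(k_neighbors, v.size - 1)
        dist = np.abs(v[:, None] - v[None, :])
        np.fill_diagonal(dist, np.inf)
        nb = np.argsort(dist, axis=1, kind="stable")[:, :k]
        base = rng.integers(0, v.size, size=need)
        pick = rng.integers(0, k, size=need)
        u = rng.uniform(size=need)
        synth = v[base] + u * (v[nb[base, pick]] - v[base])
        out_v.append(synth)
        out_l.append(np.full(need, c, dtype=labels.dtype))
    return np.concatenate(out_v), np.concatenate(out_l)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x (requires var(x) > 0)."""
    xm, ym = x.mean(), y.mean()
    xc = x - xm
    denom = float(xc @ xc)
    slope = float(xc @ (y - ym)) / denom
    return slope, float(ym - slope * xm)


def fit_participant_slope(
    values: np.ndarray,
    swb: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
    k_neighbors: int = 5,
    orientation: str = "swb_on_asym",
    participant_id: str = "",
) -> ParticipantFit:
    """Average OLS fit over ``n_repeats`` SMOTE balancings.

    ``orientation`` selects the regression direction: "swb_on_asym"
    (default; slope in SWB units per Asym unit) or "asym_on_swb". Repeats
    whose balanced predictor has zero variance are skipped with a warning;
    if every repeat is skipped the participant cannot be fit.
    """
    if orientation not in ("swb_on_asym", "asym_on_swb"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    values = np.asarray(values, float)
    swb = np.asarray(swb, int)
    children = np.random.SeedSequence(seed).spawn(n_repeats)
    slopes, intercepts = [], []
    for child in children:
        bal_v, bal_s = smote_balance(
            values, swb, k_neighbors=k_neighbors, seed=np.random.default_rng(child)
        )
        x, y = (
            (bal_v, bal_s.astype(float))
            if orientation == "swb_on_asym"
            else (bal_s.astype(float), bal_v)
        )
        if np.var(x) == 0.0:
            logger.warning(
                "participant %s: zero predictor variance after balancing; "
                "repeat skipped", participant_id,
            )
            continue
        s, i = _ols(x, y)
        slopes.append(s)
        intercepts.append(i)
    if not slopes:
        raise DegenerateDataError(
            f"participant {participant_id}: all {n_repeats} repeats skipped"
        )
    return ParticipantFit(
        participant_id=participant_id,
        slope=float(np.mean(slopes)),
        intercept=float(np.mean(intercepts)),
        n_repeats=len(slopes),
        n_samples_used=values.size,
    )


def group_slope_test(
    fits: list[ParticipantFit],
    ch1: str = "",
    ch2: str = "",
    band: str = "",
    reference: str = "original",
) -> GroupResult:
    """Two-sided one-sample t-test of the participant slopes against zero.

    The 95% CI of the mean slope is mean +/- t(0.975, n-1) * SE.
    """
    slopes = np.array([f.slope for f in fits], float)
    n = slopes.size
    if n < 2:
        raise DegenerateDataError(f"group test needs >= 2 participants, have {n}")
    if np.var(slopes, ddof=1) == 0.0:
        raise DegenerateDataError("zero variance of participant slopes")
    t_stat, p_value = sst.ttest_1samp(slopes, 0.0)
    sem = slopes.std(ddof=1) / np.sqrt(n)
    half = sst.t.ppf(0.975, n - 1) * sem
    mean = float(slopes.mean())
    return GroupResult(
        ch1=ch1, ch2=ch2, band=band, reference=reference, n_participants=n,
        mean_slope=mean, t_stat=float(t_stat), p_value=float(p_value),
        ci_low=mean - half, ci_high=mean + half,
    )


def by_fdr(
    p_values: np.ndarray, alpha: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli step-up FDR adjustment, valid under dependence.

    With m tests and c(m) = sum_{i=1..m} 1/i, the sorted adjusted p-values
    are p~_(i) = min_{j>=i}( m * c(m) * p_(j) / j ), capped at 1. Returns
    (adjusted p-values in the input order, reject flags at ``alpha``).
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ConfigurationError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_by")
    return adjusted, adjusted <= alpha
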