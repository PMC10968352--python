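"""Full-analysis orchestration: participant selection, test-family
enumeration over pairs/quadrants x bands x reference schemes, execution,
FDR correction and reporting.

A "test" is one (band, ch1, ch2) combination: ch1 is drawn from the right
hemisphere (or right quadrant) and ch2 from the left, so positive slopes
mean more right- than left-hemisphere band power at higher well-being.
Anterior and posterior universes are kept separate (no anterior-posterior
cross pairs), matching the separately reported result families; the
Benjamini-Yekutieli family is the set of tests of one run that produced a
valid group result.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ANTERIOR_LEFT,
    ANTERIOR_RIGHT,
    BAND_ORDER,
    POSTERIOR_LEFT,
    POSTERIOR_RIGHT,
    QUADRANTS,
    ConfigurationError,
    DegenerateDataError,
    Recording,
    logger,
)
from .preprocess import detect_bad_channels, detrend, extract_epochs, rereference
from .spectral import band_density, pair_log_ratio_mean
from .stats import (
    by_fdr,
    filter_swb_arrays,
    fit_participant_slope,
    group_slope_test,
)
from .synth import Dataset, ParticipantData

#: Contralateral pair universes; ch1 right, ch2 left.
PAIR_UNIVERSES: dict[str, tuple[tuple[str, str], ...]] = {
    "anterior": tuple(product(ANTERIOR_RIGHT, ANTERIOR_LEFT)),
    "posterior": tuple(product(POSTERIOR_RIGHT, POSTERIOR_LEFT)),
    "quadrants": (
        ("right_anterior", "left_anterior"),
        ("right_posterior", "left_posterior"),
    ),
    # expert option: every right-hemisphere x left-hemisphere sensor pair
    "all": tuple(
        product(ANTERIOR_RIGHT + POSTERIOR_RIGHT, ANTERIOR_LEFT + POSTERIOR_LEFT)
    ),
}

RESULT_COLUMNS = [
    "band", "ch1", "ch2", "reference", "n", "mean_slope", "t_stat",
    "p_value", "ci_low", "ci_high", "p_adjusted", "significant", "status",
]


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run (one family of tests)."""

    universe: str = "anterior"
    bands: tuple[str, ...] = BAND_ORDER
    reference: str = "original"
    alpha_fdr: float = 0.1
    n_repeats: int = 10
    epoch_duration: float = 10.0
    seed: int = 0
    k_neighbors: int = 5
    orientation: str = "swb_on_asym"
    prefilter: bool = True
    detect_bad: bool = True
    z_thresh: float = 3.0
    n_detect_iter: int = 2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.universe not in PAIR_UNIVERSES:
            raise ConfigurationError(
                f"unknown universe {self.universe!r}; known: {sorted(PAIR_UNIVERSES)}"
            )
        unknown = set(self.bands) - set(BAND_ORDER)
        if unknown or not self.bands:
            raise ConfigurationError(f"bands must be a non-empty subset of "
                                     f"{BAND_ORDER}, got {self.bands}")
        if self.reference not in ("original", "AF3", "F3"):
            raise ConfigurationError(f"unknown reference {self.reference!r}")
        if self.reference != "original" and self.universe not in (
            "posterior", "quadrants"
        ):
            raise ConfigurationError(
                "re-referencing (AF3/F3) applies only to the posterior "
                "sensors; use universe 'posterior' or 'quadrants'"
            )
        if not 0 < self.alpha_fdr < 1:
            raise ConfigurationError("alpha_fdr must be in (0, 1)")
        if self.n_repeats < 1 or self.epoch_duration <= 0:
            raise ConfigurationError("n_repeats >= 1 and epoch_duration > 0 required")

    def ordered_bands(self) -> tuple[str, ...]:
        return tuple(b for b in BAND_ORDER if b in self.bands)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def select_participants(
    dataset: Dataset,
) -> tuple[list[ParticipantData], list[dict]]:
    """Drop left-handed participants and those with too few distinct ratings.

    The rating filter pools all of a participant's reports across runs:
    ratings reported fewer than 3 times are dropped, and the participant is
    excluded if fewer than 3 distinct ratings remain. Every exclusion is
    logged with its reason.
    """
    included = []
    exclusion_log: list[dict] = []
    for p in dataset.participants:
        if p.handedness != "right":
            exclusion_log.append(
                {"participant_id": p.participant_id, "reason": "left-handed"}
            )
            continue
        ratings = np.array([rep.swb for rep in p.all_reports], int)
        _, _, excluded = filter_swb_arrays(np.zeros(ratings.size), ratings)
        if excluded:
            exclusion_log.append(
                {
                    "participant_id": p.participant_id,
                    "reason": "fewer than 3 distinct SWB values",
                }
            )
            continue
        included.append(p)
    for entry in exclusion_log:
        logger.info("excluded %(participant_id)s: %(reason)s", entry)
    if not included:
        raise DegenerateDataError(
            f"no participants remain after exclusions: {exclusion_log}"
        )
    return included, exclusion_log


def enumerate_tests(config: AnalysisConfig) -> list[tuple[str, str, str]]:
    """The test family: bands x pair universe, band-major deterministic order."""
    pairs = PAIR_UNIVERSES[config.universe]
    tests = [
        (band, c1, c2) for band in config.ordered_bands() for c1, c2 in pairs
    ]
    if not tests:
        raise ConfigurationError("empty test family")
    return tests


def _preprocess_recording(
    rec: Recording, config: AnalysisConfig, cleaner=None
) -> Recording:
    """Detrend, flag bad channels, optionally clean, re-reference."""
    rec = detrend(rec)
    if config.detect_bad:
        rec.bad_channels |= detect_bad_channels(
            rec, z_thresh=config.z_thresh, n_iter=config.n_detect_iter
        )
    if cleaner is not None:  # hook for an external artifact-removal step
        rec = cleaner(rec)
    if config.reference != "original":
        rec = rereference(rec, config.reference)
    return rec


def _run_signals(
    earr: np.ndarray, rec: Recording, names: set[str]
) -> dict[str, np.ndarray | None]:
    """Per-epoch signal matrix for each channel or quadrant name.

    Bad channels map to None; a quadrant is the mean of its non-bad members,
    None if every member is bad.
    """
    out: dict[str, np.ndarray | None] = {}
    for name in names:
        if name in QUADRANTS:
            idx = [
                rec.index_of(ch)
                for ch in QUADRANTS[name]
                if ch in rec.channel_labels and ch not in rec.bad_channels
            ]
            out[name] = earr[:, idx].mean(axis=1) if idx else None
        elif name not in rec.channel_labels or name in rec.bad_channels:
            out[name] = None
        else:
            out[name] = earr[:, rec.index_of(name)]
    return out


def run_analysis(
    dataset: Dataset,
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
    cleaner=None,
) -> pd.DataFrame:
    """Execute the full analysis and return one row per enumerated test.

    For each test, per-epoch asymmetry samples are pooled over all runs of
    each included participant, filtered, SMOTE-balanced and fit per
    participant, then tested at the group level; raw p-values of the valid
    rows form one BY FDR family. Rows are sorted by adjusted p-value. All
    randomness derives from ``config.seed``; reruns are bit-identical.
    """
    config.validate()
    included, exclusion_log = select_participants(dataset)
    tests = enumerate_tests(config)
    names = {n for _, c1, c2 in tests for n in (c1, c2)}
    bands = config.ordered_bands()
    log_lines: list[str] = []

    # acc[test_index][participant_index] = list of (values, swb) arrays
    acc: list[dict[int, list[tuple[np.ndarray, np.ndarray]]]] = [
        {} for _ in tests
    ]
    tests_by_band = {
        band: [i for i, t in enumerate(tests) if t[0] == band] for band in bands
    }

    for p_idx, part in enumerate(included):
        for run in part.runs:
            if run.recording is None:
                continue
            try:
                rec = _preprocess_recording(run.recording, config, cleaner)
            except DegenerateDataError as exc:
                logger.warning("skipping run %s/%s: %s",
                               part.participant_id, run.run_id, exc)
                log_lines.append(f"skipped_run\t{part.participant_id}/{run.run_id}"
                                 f"\t{exc}")
                continue
            if rec.bad_channels:
                log_lines.append(
                    f"bad_channels\t{part.participant_id}/{run.run_id}\t"
                    f"{sorted(rec.bad_channels)}"
                )
            epochs = extract_epochs(rec, run.reports, config.epoch_duration)
            if not epochs:
                continue
            earr = np.stack([e.samples for e in epochs])
            swb_vec = np.array([e.swb for e in epochs], int)
            signals = _run_signals(earr, rec, names)
            for band in bands:
                valid_names = sorted(n for n in names if signals[n] is not None)
                if not valid_names:
                    continue
                stacked = np.stack([signals[n] for n in valid_names], axis=1)
                _, dens = band_density(
                    stacked, rec.fs, band, prefilter=config.prefilter
                )
                col = {n: i for i, n in enumerate(valid_names)}
                for t_idx in tests_by_band[band]:
                    _, c1, c2 = tests[t_idx]
                    if c1 not in col or c2 not in col:
                        continue
                    vals = pair_log_ratio_mean(dens[:, col[c1]], dens[:, col[c2]])
                    ok = np.isfinite(vals)
                    if not np.all(ok):
                        log_lines.append(
                            f"degenerate_epochs\t{part.participant_id}/"
                            f"{run.run_id}\t{band}:{c1}-{c2}"
                        )
                    acc[t_idx].setdefault(p_idx, []).append(
                        (vals[ok], swb_vec[ok])
                    )

    rows: list[dict] = []
    for t_idx, (band, c1, c2) in enumerate(tests):
        fits = []
        for p_idx, part in enumerate(included):
            chunks = acc[t_idx].get(p_idx)
            if not chunks:
                continue
            values = np.concatenate([v for v, _ in chunks])
            swb = np.concatenate([s for _, s in chunks])
            values, swb, excluded = filter_swb_arrays(values, swb)
            if excluded:
                continue
            seed = int(
                np.random.SeedSequence(
                    [config.seed, t_idx, p_idx]
                ).generate_state(1)[0]
            )
            try:
                fit = fit_participant_slope(
                    values, swb,
                    n_repeats=config.n_repeats, seed=seed,
                    k_neighbors=config.k_neighbors,
                    orientation=config.orientation,
                    participant_id=part.participant_id,
                )
            except DegenerateDataError:
                continue
            fits.append(fit)
        row = {
            "band": band, "ch1": c1, "ch2": c2, "reference": config.reference,
            "test_index": t_idx,
        }
        try:
            res = group_slope_test(
                fits, ch1=c1, ch2=c2, band=band, reference=config.reference
            )
            row.update(
                n=res.n_participants, mean_slope=res.mean_slope,
                t_stat=res.t_stat, p_value=res.p_value,
                ci_low=res.ci_low, ci_high=res.ci_high, status="ok",
            )
        except DegenerateDataError:
            row.update(
                n=len(fits), mean_slope=np.nan, t_stat=np.nan, p_value=np.nan,
                ci_low=np.nan, ci_high=np.nan, status="insufficient_data",
            )
        rows.append(row)

    results = pd.DataFrame(rows)
    ok = results["status"] == "ok"
    results["p_adjusted"] = np.nan
    results["significant"] = False
    if ok.any():
        adjusted, reject = by_fdr(
            results.loc[ok, "p_value"].to_numpy(), alpha=config.alpha_fdr
        )
        results.loc[ok, "p_adjusted"] = adjusted
        results.loc[ok, "significant"] = reject
    results = results.sort_values(
        ["status", "p_adjusted", "test_index"],
        ascending=[True, True, True], kind="stable", na_position="last",
    ).reset_index(drop=True)
    results = results[RESULT_COLUMNS]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(results, out_dir, alpha=config.alpha_fdr)
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        with open(out_dir / "run_log.tsv", "w") as fh:
            fh.write(f"{stamp}\tconfig_hash\t{config.hash()}\n")
            fh.write(f"{stamp}\tseed\t{config.seed}\n")
            for entry in exclusion_log:
                fh.write(
                    f"{stamp}\texcluded\t{entry['participant_id']}"
                    f"\t{entry['reason']}\n"
                )
            for line in log_lines:
                fh.write(f"{stamp}\t{line}\n")
    return results


def write_report(
    results: pd.DataFrame, path: str | Path, alpha: float = 0.1
) -> tuple[Path, Path]:
    """Write the results TSV and a human-readable significance summary."""
    if results.empty:
        raise ConfigurationError("no results to report")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tsv = path / "results.tsv"
    results.to_csv(tsv, sep="\t", index=False)
    summary = path / "summary.txt"
    sig = results[results["significant"] == True]  # noqa: E712
    with open(summary, "w") as fh:
        fh.write("Group tests of the SWB-asymmetry slope\n")
        fh.write("=" * 46 + "\n")
        if sig.empty:
            fh.write(f"no tests significant at alpha = {alpha}\n")
        else:
            fh.write(
                f"{'Band':8s}{'ch1':16s}{'ch2':16s}{'p-value':>10s}"
                f"{'CI_low':>9s}{'CI_high':>9s}{'p_adj':>10s}\n"
            )
            for _, r in sig.iterrows():
                fh.write(
                    f"{r['band']:8s}{r['ch1']:16s}{r['ch2']:16s}"
                    f"{r['p_value']:10.4f}{r['ci_low']:9.3f}"
                    f"{r['ci_high']:9.3f}{r['p_adjusted']:10.4f}\n"
                )
    return tsv, summary


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_report`."""
    return pd.read_csv(Path(path), sep="\t")
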