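"""Synthetic participants: SWB rating sequences and band-limited EEG.

The generator emulates the study conditions end to end so that every
downstream stage (preprocessing, spectral asymmetry, balanced-regression
inference) is testable without any recorded data: runs of up to 9 minutes at
128 Hz on the 14-channel montage, one integer SWB rating (1-10) every 30 s
drawn from an imbalanced distribution, and a configurable linear coupling
between the right/left band-power log-ratio of chosen channel pairs and the
concurrent SWB rating.

Each channel is a sum over bands of independent band-limited Gaussian noise,
synthesized in the frequency domain (complex Gaussian rFFT coefficients on
the in-band bins, zero elsewhere), which is white noise ideally band-pass
filtered to the band and has an exactly flat in-band spectrum. For an
injected coupling (chR, chL, band, gamma), within each 30 s inter-report
segment ending at a report with rating s the band component of chR is scaled
by exp(+(gamma*s + e)/4) and that of chL by exp(-(gamma*s + e)/4) with
e ~ Normal(0, asym_noise_sd), so the expected log power ratio - the Asym
statistic of that pair and band - is exactly gamma*s + e. Splitting the
scaling between the two coupled channels (rather than loading it all on chR)
halves the slope leaked into pairs that share only one coupled channel,
keeping the injected pair uniquely strongest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MONTAGE,
    SWB_RATINGS,
    ConfigurationError,
    ParseError,
    Recording,
    SWBReport,
    get_band,
    logger,
)
from .spectral import clip_band

#: Qualitatively imbalanced default rating distribution: 6/7/8 dominate.
DEFAULT_SWB_PROBS: dict[int, float] = {
    1: 0.01, 2: 0.01, 3: 0.03, 4: 0.04, 5: 0.10,
    6: 0.28, 7: 0.28, 8: 0.18, 9: 0.06, 10: 0.01,
}

#: Baseline per-band RMS amplitudes in microvolts (posterior-dominant alpha
#: and strong slow activity, weak gamma - a generic resting-state profile).
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 20.0, "theta": 10.0, "alpha": 10.0, "beta": 5.0, "gamma": 2.0,
}


@dataclass(frozen=True)
class Coupling:
    """Injected Asym-per-SWB-unit slope for one (right, left, band) triple."""

    ch_right: str
    ch_left: str
    band: str
    gamma: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.ch_right, self.ch_left)


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic dataset generator."""

    n_participants: int = 30
    n_runs_per_participant: int = 6
    run_duration: float = 540.0          # seconds (9 min)
    report_interval: float = 30.0        # seconds
    sampling_rate: float = 128.0         # Hz
    swb_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SWB_PROBS))
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    couplings: list[Coupling] = field(default_factory=list)
    asym_noise_sd: float = 0.1
    left_handed_fraction: float = 2.0 / 30.0
    seed: int = 0
    #: optional per-participant-index rating-distribution overrides
    swb_probs_overrides: dict[int, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for probs in [self.swb_probs, *self.swb_probs_overrides.values()]:
            vals = np.array([probs.get(r, 0.0) for r in SWB_RATINGS], float)
            if np.any(vals < 0):
                raise ConfigurationError("swb_probs must be non-negative")
            if abs(vals.sum() - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"swb_probs must sum to 1 within 1e-12, got {vals.sum()!r}"
                )
            if set(probs) - set(SWB_RATINGS):
                raise ConfigurationError("swb_probs keys must be ratings 1..10")
        n_rep = self.run_duration / self.report_interval
        if abs(n_rep - round(n_rep)) > 1e-9 or round(n_rep) < 1:
            raise ConfigurationError(
                "run_duration / report_interval must be an integer >= 1"
            )
        if self.n_participants < 1 or self.n_runs_per_participant < 1:
            raise ConfigurationError("need at least one participant and run")
        if not 0 <= self.left_handed_fraction <= 1:
            raise ConfigurationError("left_handed_fraction must be in [0, 1]")
        if self.asym_noise_sd < 0:
            raise ConfigurationError("asym_noise_sd must be >= 0")
        for name, amp in self.band_amplitudes.items():
            band = get_band(name)
            if amp < 0:
                raise ConfigurationError(f"negative amplitude for band {name}")
            lo, hi = clip_band(band, self.sampling_rate)
            if self.sampling_rate <= 2 * hi:
                raise ConfigurationError(
                    f"sampling_rate {self.sampling_rate} too low for band "
                    f"{name} (upper edge {hi} Hz)"
                )
        for c in self.couplings:
            for ch in (c.ch_right, c.ch_left):
                if ch not in MONTAGE:
                    raise ConfigurationError(
                        f"coupling names channel {ch!r} outside the montage"
                    )
            if c.band not in self.band_amplitudes:
                raise ConfigurationError(
                    f"coupling band {c.band!r} is not synthesized "
                    f"(band_amplitudes: {sorted(self.band_amplitudes)})"
                )

    @property
    def n_reports_per_run(self) -> int:
        return int(round(self.run_duration / self.report_interval))


@dataclass
class SynthTruth:
    """Ground truth of a generated dataset, for recovery tests."""

    couplings: dict[tuple[str, str, str], float]     # (chR, chL, band) -> gamma
    handedness: dict[str, str]                       # participant_id -> right/left
    swb_sequences: dict[tuple[str, str], list[int]]  # (pid, rid) -> ratings
    seed: int = 0


@dataclass
class RunData:
    run_id: str
    reports: list[SWBReport]
    recording: Recording | None = None


@dataclass
class ParticipantData:
    participant_id: str
    handedness: str
    runs: list[RunData]

    @property
    def all_reports(self) -> list[SWBReport]:
        return [rep for run in self.runs for rep in run.reports]


@dataclass
class Dataset:
    participants: list[ParticipantData]
    fs: float = 128.0
    truth: SynthTruth | None = None


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _probs_vector(probs: dict[int, float]) -> np.ndarray:
    return np.array([probs.get(r, 0.0) for r in SWB_RATINGS], float)


def generate_swb_sequence(
    config: SynthConfig,
    participant_seed: int,
    swb_probs: dict[int, float] | None = None,
) -> list[SWBReport]:
    """Draw one run's rating sequence, one report every ``report_interval`` s.

    Ratings are i.i.d. from ``swb_probs`` (``config.swb_probs`` by default);
    reports sit at t = k * report_interval for k = 1..n_reports_per_run.
    Reproducible given the seed.
    """
    probs = _probs_vector(swb_probs if swb_probs is not None else config.swb_probs)
    rng = np.random.default_rng(participant_seed)
    ratings = rng.choice(np.array(SWB_RATINGS), size=config.n_reports_per_run, p=probs)
    return [
        SWBReport(time_s=(k + 1) * config.report_interval, swb=int(r))
        for k, r in enumerate(ratings)
    ]


def _band_limited_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float,
    f_low: float, f_high: float, rms: float,
) -> np.ndarray:
    """Gaussian noise with a flat spectrum confined to [f_low, f_high].

    Complex standard-normal rFFT coefficients on the in-band bins (zero
    elsewhere), scaled so the expected per-sample variance is ``rms**2``.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    in_band = (freqs >= f_low) & (freqs <= f_high) & (freqs > 0) & (freqs < fs / 2)
    n_bins = int(in_band.sum())
    if n_bins == 0:
        raise ConfigurationError(
            f"no FFT bins inside [{f_low}, {f_high}] Hz at n={n_samples}"
        )
    coef = np.zeros((n_channels, freqs.size), dtype=complex)
    z = rng.standard_normal((n_channels, n_bins)) + 1j * rng.standard_normal(
        (n_channels, n_bins)
    )
    # irfft variance per sample of unit complex coefficients is 2*n_bins/n^2
    coef[:, in_band] = z * (rms * n_samples / np.sqrt(2.0 * n_bins))
    return np.fft.irfft(coef, n=n_samples, axis=-1)


def generate_recording(
    swb: list[SWBReport],
    config: SynthConfig,
    run_seed: int,
    participant_id: str = "",
    run_id: str = "",
) -> Recording:
    """Synthesize one run of 14-channel EEG realizing the injected couplings.

    Channels are sums over bands of independent band-limited Gaussian noise
    with RMS ``band_amplitudes[band]``; for each coupling the two coupled
    channels' band components are scaled per 30 s segment so the expected
    asymmetry equals gamma * rating (plus Normal(0, asym_noise_sd) noise).
    Bit-reproducible given the seed.
    """
    if not swb:
        raise ConfigurationError("need a non-empty SWB sequence")
    fs = config.sampling_rate
    n = int(round(config.run_duration * fs))
    seg = int(round(config.report_interval * fs))
    nch = len(MONTAGE)
    rng = np.random.default_rng(run_seed)
    ratings = np.array([rep.swb for rep in swb], float)

    samples = np.zeros((nch, n))
    for band_name in sorted(config.band_amplitudes):  # deterministic order
        amp = config.band_amplitudes[band_name]
        lo, hi = clip_band(get_band(band_name), fs)
        comp = _band_limited_noise(rng, nch, n, fs, lo, hi, amp)
        for c in config.couplings:
            if c.band != band_name:
                continue
            e = (
                rng.normal(0.0, config.asym_noise_sd, size=ratings.size)
                if config.asym_noise_sd > 0
                else np.zeros(ratings.size)
            )
            log_ratio = c.gamma * ratings + e          # target per-segment Asym
            i_r = MONTAGE.index(c.ch_right)
            i_l = MONTAGE.index(c.ch_left)
            for k, x in enumerate(log_ratio):
                sl = slice(k * seg, min((k + 1) * seg, n))
                comp[i_r, sl] *= np.exp(+x / 4.0)
                comp[i_l, sl] *= np.exp(-x / 4.0)
        samples += comp

    return Recording(
        participant_id=participant_id,
        run_id=run_id,
        fs=fs,
        channel_labels=MONTAGE,
        samples=samples,
    )


def inject_bad_channel(
    rec: Recording, channel: str, mode: str, seed: int = 0
) -> Recording:
    """Return a copy with ``channel`` corrupted: flat, high_variance or spikes."""
    idx = rec.index_of(channel)
    out = rec.copy()
    rng = np.random.default_rng(seed)
    x = out.samples[idx]
    if mode == "flat":
        out.samples[idx] = 0.0
    elif mode == "high_variance":
        sd = float(np.std(x))
        if sd == 0.0:
            sd = float(np.median(np.std(out.samples, axis=1)))
        out.samples[idx] = rng.normal(0.0, 50.0 * sd, size=x.size)
    elif mode == "spikes":
        n_spikes = max(5, x.size // 100)  # ~1% of samples
        pos = rng.choice(x.size, size=n_spikes, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_spikes)
        out.samples[idx] = x.copy()
        out.samples[idx, pos] += 500.0 * signs
    else:
        raise ConfigurationError(
            f"unknown bad-channel mode {mode!r}; use flat, high_variance or spikes"
        )
    return out


def generate_participant(
    config: SynthConfig,
    participant_index: int,
    handedness: str = "right",
    with_eeg: bool = True,
) -> ParticipantData:
    """Generate one participant's runs with deterministic child seeds."""
    pid = f"P{participant_index + 1:02d}"
    probs = config.swb_probs_overrides.get(participant_index)
    runs = []
    for r in range(config.n_runs_per_participant):
        swb_seed = np.random.SeedSequence([config.seed, participant_index, r, 0])
        eeg_seed = np.random.SeedSequence([config.seed, participant_index, r, 1])
        reports = generate_swb_sequence(
            config, swb_seed.generate_state(1)[0], swb_probs=probs
        )
        recording = None
        if with_eeg:
            recording = generate_recording(
                reports, config, eeg_seed.generate_state(1)[0],
                participant_id=pid, run_id=f"R{r + 1}",
            )
        runs.append(RunData(run_id=f"R{r + 1}", reports=reports, recording=recording))
    return ParticipantData(participant_id=pid, handedness=handedness, runs=runs)


def generate_dataset(config: SynthConfig, with_eeg: bool = True) -> Dataset:
    """Generate the full synthetic dataset with ground truth attached.

    Exactly round(left_handed_fraction * n_participants) participants are
    left-handed, chosen by the seeded RNG. All randomness descends from
    ``config.seed`` through per-(participant, run) seed children.
    """
    n = config.n_participants
    n_left = int(round(config.left_handed_fraction * n))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xAD]))
    left_idx = set(rng.choice(n, size=n_left, replace=False).tolist())
    participants = []
    for p in range(n):
        handed = "left" if p in left_idx else "right"
        participants.append(
            generate_participant(config, p, handedness=handed, with_eeg=with_eeg)
        )
    truth = SynthTruth(
        couplings={(c.ch_right, c.ch_left, c.band): c.gamma for c in config.couplings},
        handedness={pp.participant_id: pp.handedness for pp in participants},
        swb_sequences={
            (pp.participant_id, run.run_id): [rep.swb for rep in run.reports]
            for pp in participants
            for run in pp.runs
        },
        seed=config.seed,
    )
    return Dataset(participants=participants, fs=config.sampling_rate, truth=truth)


# ----------------------------------------------------------------------
# dataset I/O: CSV or EDF per run + TSV reports + metadata
# ----------------------------------------------------------------------

def _write_edf(path: Path, rec: Recording) -> None:
    """Minimal EDF writer: 1 s data records, int16, physical unit uV."""
    fs = int(round(rec.fs))
    nch, nsamp = rec.samples.shape
    if nsamp % fs:
        raise ConfigurationError("EDF export needs a whole number of seconds")
    nrec = nsamp // fs
    pmax = float(np.max(np.abs(rec.samples))) * 1.0001 + 1e-6
    labels = rec.channel_labels

    def fixed(vals, width) -> bytes:
        out = b""
        for v in vals:
            s = str(v).encode("ascii")[:width]
            out += s.ljust(width)
        return out

    h = b"0".ljust(8)
    h += b"X X X X".ljust(80)
    h += b"Startdate X X X X".ljust(80)
    h += b"01.01.00" + b"00.00.00"
    h += str(256 * (nch + 1)).encode().ljust(8)
    h += b"".ljust(44)
    h += str(nrec).encode().ljust(8)
    h += b"1".ljust(8)                      # record duration: 1 s
    h += str(nch).encode().ljust(4)
    h += fixed(labels, 16)
    h += fixed([""] * nch, 80)              # transducer
    h += fixed(["uV"] * nch, 8)
    h += fixed([f"{-pmax:.6g}"] * nch, 8)
    h += fixed([f"{pmax:.6g}"] * nch, 8)
    h += fixed([-32768] * nch, 8)
    h += fixed([32767] * nch, 8)
    h += fixed([""] * nch, 80)              # prefiltering
    h += fixed([fs] * nch, 8)
    h += b"".ljust(32 * nch)
    # match the reader's scale: step = (phys_max - phys_min) / (dig_max - dig_min)
    lo, hi = float(f"{-pmax:.6g}"), float(f"{pmax:.6g}")
    step = (hi - lo) / 65535.0
    dig = np.clip(np.round((rec.samples - lo) / step) - 32768, -32768, 32767)
    dig = dig.astype("<i2")
    with open(path, "wb") as fh:
        fh.write(h)
        for r in range(nrec):
            fh.write(np.ascontiguousarray(dig[:, r * fs:(r + 1) * fs]).tobytes())


def _read_edf(path: Path) -> tuple[tuple[str, ...], np.ndarray, float]:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface file identity
        raise ParseError(f"cannot parse EDF file {path.name}: {exc}") from exc
    return tuple(raw.ch_names), raw.get_data() * 1e6, float(raw.info["sfreq"])


def _eeg_filename(pid: str, rid: str, dialect: str) -> str:
    return f"{pid}_{rid}.{ 'edf' if dialect == 'edf' else 'csv'}"


def write_dataset(dataset: Dataset, path: str | Path, dialect: str = "csv") -> None:
    """Write a dataset directory: metadata.tsv, swb.tsv and one EEG file per run.

    ``dialect`` selects "csv" (wide table, one column per channel, header row
    of labels, sample index implicit at fs; lossless) or "edf" (16-bit
    quantized European Data Format).
    """
    if dialect not in ("csv", "edf"):
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    root = Path(path)
    (root / "eeg").mkdir(parents=True, exist_ok=True)

    meta_seed = dataset.truth.seed if dataset.truth is not None else ""
    pd.DataFrame(
        [
            {"participant_id": p.participant_id, "handedness": p.handedness,
             "seed": meta_seed}
            for p in dataset.participants
        ]
    ).to_csv(root / "metadata.tsv", sep="\t", index=False)

    rows = [
        {"participant_id": p.participant_id, "run_id": run.run_id,
         "time_s": rep.time_s, "swb": rep.swb}
        for p in dataset.participants for run in p.runs for rep in run.reports
    ]
    pd.DataFrame(rows).to_csv(root / "swb.tsv", sep="\t", index=False)

    json.dump(
        {"sampling_rate": dataset.fs, "dialect": dialect, "seed": meta_seed},
        open(root / "provenance.json", "w"), indent=1,
    )

    for p in dataset.participants:
        for run in p.runs:
            rec = run.recording
            if rec is None:
                continue
            fname = root / "eeg" / _eeg_filename(p.participant_id, run.run_id, dialect)
            if dialect == "edf":
                _write_edf(fname, rec)
            else:
                pd.DataFrame(rec.samples.T, columns=list(rec.channel_labels)).to_csv(
                    fname, index=False, float_format="%.17g"
                )


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`.

    EEG channel labels outside the montage are ignored with a warning.
    Malformed records raise :class:`ParseError` naming the offending file/row.
    """
    root = Path(path)
    try:
        prov = json.load(open(root / "provenance.json"))
        fs = float(prov["sampling_rate"])
        dialect = prov["dialect"]
    except FileNotFoundError:
        fs, dialect = 128.0, "csv"

    try:
        meta = pd.read_csv(root / "metadata.tsv", sep="\t")
        swb = pd.read_csv(root / "swb.tsv", sep="\t")
    except FileNotFoundError as exc:
        raise ParseError(f"dataset at {root} is missing {exc.filename}") from exc
    for col in ("participant_id", "handedness"):
        if col not in meta.columns:
            raise ParseError(f"metadata.tsv lacks required column {col!r}")
    for col in ("participant_id", "run_id", "time_s", "swb"):
        if col not in swb.columns:
            raise ParseError(f"swb.tsv lacks required column {col!r}")

    participants = []
    for _, mrow in meta.iterrows():
        pid = str(mrow["participant_id"])
        p_swb = swb[swb["participant_id"].astype(str) == pid]
        runs = []
        for rid in sorted(p_swb["run_id"].astype(str).unique()):
            r_swb = p_swb[p_swb["run_id"].astype(str) == rid].sort_values("time_s")
            try:
                reports = [
                    SWBReport(time_s=float(t), swb=int(v))
                    for t, v in zip(r_swb["time_s"], r_swb["swb"])
                ]
            except (ValueError, ConfigurationError) as exc:
                raise ParseError(
                    f"swb.tsv: bad report for participant {pid} run {rid}: {exc}"
                ) from exc
            recording = _read_recording(root, pid, rid, dialect, fs)
            runs.append(RunData(run_id=rid, reports=reports, recording=recording))
        participants.append(
            ParticipantData(
                participant_id=pid, handedness=str(mrow["handedness"]), runs=runs
            )
        )
    return Dataset(participants=participants, fs=fs, truth=None)


def _read_recording(
    root: Path, pid: str, rid: str, dialect: str, fs: float
) -> Recording | None:
    fname = root / "eeg" / _eeg_filename(pid, rid, dialect)
    if not fname.exists():
        return None
    if dialect == "edf":
        labels, data, fs_read = _read_edf(fname)
        fs = fs_read
    else:
        try:
            df = pd.read_csv(fname, float_precision="round_trip")
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"cannot parse CSV file {fname.name}: {exc}") from exc
        labels, data = tuple(df.columns), df.to_numpy(float).T
    keep = [i for i, lab in enumerate(labels) if lab in MONTAGE]
    dropped = [lab for lab in labels if lab not in MONTAGE]
    if dropped:
        logger.warning(
            "%s: ignoring non-montage channel(s) %s", fname.name, dropped
        )
    if not np.all(np.isfinite(data[keep])):
        raise ParseError(f"{fname.name}: non-finite samples")
    return Recording(
        participant_id=pid,
        run_id=rid,
        fs=fs,
        channel_labels=tuple(labels[i] for i in keep),
        samples=data[keep],
    )
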