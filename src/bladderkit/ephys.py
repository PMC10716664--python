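"""Threshold and tuning analysis of saccular evoked-potential recordings.

A recording session yields, per stimulus frequency and sound pressure level
(dB re 1 uPa), eight repetitions of the lock-in second-harmonic magnitude
(uV), plus eight background-only measurements taken before stimulation.
The threshold at a frequency is the lowest level of the grid whose mean
magnitude is at least two background standard deviations above the
background mean; if no level qualifies the frequency is scored
"no response".  Group summaries (tuning curves with t-based confidence
intervals, iso-level profiles, detection rates, between-group threshold
differences) follow from that rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

NO_RESPONSE = float("nan")


@dataclass
class EvokedDataset:
    """Background magnitudes + per-(frequency, level, rep) trial table."""

    background: np.ndarray                  # uV, n >= 2
    trials: pd.DataFrame                    # frequency_hz, level_db, rep, magnitude_uv
    metadata: dict = field(default_factory=dict)

    REQUIRED = ("frequency_hz", "level_db", "rep", "magnitude_uv")

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.size < 2:
            raise ValueError("need >= 2 background measurements (SD undefined)")
        missing = [c for c in self.REQUIRED if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        if (self.trials["magnitude_uv"] < 0).any():
            raise ValueError("magnitudes must be non-negative")

    @property
    def frequencies(self) -> np.ndarray:
        return np.sort(self.trials["frequency_hz"].unique())

    @property
    def levels(self) -> np.ndarray:
        return np.sort(self.trials["level_db"].unique())

    def to_csv(self, trials_path, background_path) -> None:
        self.trials.to_csv(trials_path, index=False)
        pd.DataFrame({"magnitude_uv": self.background}).to_csv(
            background_path, index=False)

    @classmethod
    def from_csv(cls, trials_path, background_path, metadata=None) -> "EvokedDataset":
        return cls(
            background=pd.read_csv(background_path)["magnitude_uv"].to_numpy(),
            trials=pd.read_csv(trials_path),
            metadata=dict(metadata or {}),
        )


def background_stats(background: np.ndarray) -> tuple[float, float]:
    """Sample mean and sample SD (n-1 denominator) of the background trials."""
    background = np.asarray(background, dtype=float)
    if background.size < 2:
        raise ValueError("need >= 2 background measurements")
    return float(background.mean()), float(background.std(ddof=1))


def determine_threshold(dataset: EvokedDataset, frequency: float) -> float:
    """Lowest level whose mean magnitude >= background mean + 2 SD.

    Returns NaN ("no response") when no level qualifies.  The criterion is
    inclusive ("at least two standard deviations above").
    """
    sub = dataset.trials[dataset.trials["frequency_hz"] == frequency]
    if sub.empty:
        raise ValueError(f"no trials at frequency {frequency} Hz")
    grid = dataset.levels
    present = np.sort(sub["level_db"].unique())
    gaps = np.setdiff1d(grid, present)
    if gaps.size:
        raise ValueError(f"missing levels at {frequency} Hz: {gaps.tolist()}")
    mu, sd = background_stats(dataset.background)
    criterion = mu + 2.0 * sd
    means = sub.groupby("level_db")["magnitude_uv"].mean()
    qualifying = means.index[means.to_numpy() >= criterion]
    return float(qualifying.min()) if len(qualifying) else NO_RESPONSE


@dataclass
class TuningCurve:
    """Per-frequency threshold (dB re 1 uPa; NaN = no response) for one record."""

    frequencies: np.ndarray
    thresholds: np.ndarray
    background_mean: float
    background_sd: float
    metadata: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.thresholds, index=self.frequencies, name="threshold_db")


def tuning_curve(dataset: EvokedDataset) -> TuningCurve:
    """Threshold at every frequency of the dataset's grid."""
    mu, sd = background_stats(dataset.background)
    freqs = dataset.frequencies
    thr = np.array([determine_threshold(dataset, f) for f in freqs])
    return TuningCurve(frequencies=freqs, thresholds=thr,
                       background_mean=mu, background_sd=sd,
                       metadata=dict(dataset.metadata))


def iso_level_profile(dataset: EvokedDataset, level: float) -> pd.DataFrame:
    """Mean and SE of the evoked magnitude across repetitions at one level."""
    if level not in set(dataset.levels.tolist()):
        raise ValueError(f"level {level} dB is not on the stimulus grid")
    sub = dataset.trials[dataset.trials["level_db"] == level]
    out = sub.groupby("frequency_hz")["magnitude_uv"].agg(
        mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
    return out.reset_index()


def group_iso_level_profile(datasets: list[EvokedDataset], level: float) -> pd.DataFrame:
    """Mean and SE over records of the per-record mean magnitudes."""
    per = [iso_level_profile(d, level).set_index("frequency_hz")["mean"]
           for d in datasets]
    tbl = pd.concat(per, axis=1)
    out = pd.DataFrame({
        "frequency_hz": tbl.index,
        "mean": tbl.mean(axis=1).to_numpy(),
        "se": (tbl.std(axis=1, ddof=1) / np.sqrt(tbl.shape[1])).to_numpy(),
        "n": tbl.notna().sum(axis=1).to_numpy(),
    })
    return out.reset_index(drop=True)


def group_tuning_curve(curves: list[TuningCurve], ci: float = 0.95) -> pd.DataFrame:
    """Mean threshold per frequency over defined records, with t-based CI.

    "No response" records are excluded per frequency (no imputation); the
    per-frequency n is reported.
    """
    if not curves:
        raise ValueError("need at least one tuning curve")
    freqs = curves[0].frequencies
    for c in curves[1:]:
        if not np.array_equal(c.frequencies, freqs):
            raise ValueError("tuning curves are on different frequency grids")
    thr = np.vstack([c.thresholds for c in curves])          # (n_rec, n_freq)
    n = np.sum(~np.isnan(thr), axis=0)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frequencies
        mean = np.nanmean(thr, axis=0)
        sd = np.nanstd(thr, axis=0, ddof=1)
    half = np.full_like(mean, np.nan)
    ok = n >= 2
    tcrit = sps.t.ppf(0.5 + ci / 2.0, n[ok] - 1)
    half[ok] = tcrit * sd[ok] / np.sqrt(n[ok])
    return pd.DataFrame({
        "frequency_hz": freqs, "mean_threshold_db": mean,
        "ci_half_width_db": half, "n": n,
    })


def detection_rate(curves: list[TuningCurve]) -> pd.DataFrame:
    """Percentage of records with a defined threshold, per frequency."""
    if not curves:
        raise ValueError("need at least one tuning curve")
    freqs = curves[0].frequencies
    thr = np.vstack([c.thresholds for c in curves])
    rate = 100.0 * np.mean(~np.isnan(thr), axis=0)
    return pd.DataFrame({"frequency_hz": freqs, "detection_rate_pct": rate})


def threshold_difference(
    curves_a: list[TuningCurve], curves_b: list[TuningCurve]
) -> pd.DataFrame:
    """Per-frequency difference of group mean thresholds (A - B, dB) and the
    equivalent pressure-amplitude fold change 10^(dB/20).

    A twofold sensitivity change corresponds to 20*log10(2) ~ 6.02 dB.
    Frequencies where either group has no defined record are left NaN.
    """
    ga = group_tuning_curve(curves_a)
    gb = group_tuning_curve(curves_b)
    if not np.array_equal(ga["frequency_hz"], gb["frequency_hz"]):
        raise ValueError("groups measured on different frequency grids")
    delta = ga["mean_threshold_db"] - gb["mean_threshold_db"]
    return pd.DataFrame({
        "frequency_hz": ga["frequency_hz"],
        "delta_db": delta,
        "fold_change": 10.0 ** (np.abs(delta) / 20.0),
        "n_a": ga["n"], "n_b": gb["n"],
    })
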