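"""Median-split power binning and the power-strength coupling analysis.

Trials are ranked by pre-distractor band power at the virtual sensor and
median-split into low/high bins.  The memory-strength proxy (mean AUC of
probe-trained classifiers over the pre-distractor test window) is computed
per bin from a classifier trained on *all* trials, and two group-level
questions are asked: (1) does strength differ overall between bins
(RM-ANOVA over band x bin, paired t per band), and (2) do subjects with a
larger power modulation M = log10(mean high power / mean low power) show a
larger strength difference between bins (Pearson r of M against the
high-minus-low strength difference, per band)?

The correlation is oriented high-minus-low so that a *negative* r means
"stronger power modulation goes with a larger strength advantage of the
low-power bin".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import EpochSet
from .sigproc import BandPowerTable
from .decode import (memory_strength, time_generalization)
from .stats import pearson


@dataclass
class BinAssignment:
    bins: np.ndarray             # per-trial "low" / "high"
    band: str
    n_low: int
    n_high: int

    @property
    def low(self) -> np.ndarray:
        return self.bins == "low"

    @property
    def high(self) -> np.ndarray:
        return self.bins == "high"


def median_split(powers: BandPowerTable) -> BinAssignment:
    """Rank trials by power (ties broken by trial index); the lower half is
    'low', the upper half 'high'.  For odd n the median-rank trial goes to
    the low bin, so |n_low - n_high| <= 1.  Never errors on ties."""
    p = np.asarray(powers.power, dtype=float)
    n = p.size
    if n < 2:
        raise ValueError("need at least two trials")
    order = np.lexsort((np.arange(n), p))     # stable: ties by trial index
    n_low = (n + 1) // 2
    bins = np.empty(n, dtype=object)
    bins[order[:n_low]] = "low"
    bins[order[n_low:]] = "high"
    return BinAssignment(bins=bins.astype(str), band=powers.band.name,
                         n_low=n_low, n_high=n - n_low)


def modulation_ratio(powers: BandPowerTable, assignment: BinAssignment
                     ) -> float:
    """M = log10(mean power | high / mean power | low); >= 0 by construction
    of the split."""
    p = np.asarray(powers.power, dtype=float)
    lo = p[assignment.low].mean()
    hi = p[assignment.high].mean()
    if lo <= 0 or hi <= 0:
        raise ValueError("mean bin power must be positive")
    return float(np.log10(hi / lo))


def bin_strengths(epochs: EpochSet, labels: np.ndarray,
                  assignment: BinAssignment,
                  train_window: tuple[float, float],
                  test_window: tuple[float, float],
                  strength_train_window: tuple[float, float] | None = None,
                  shrinkage="auto", decode_sfreq: float | None = 100.0
                  ) -> dict:
    """Memory strength per power bin from a classifier trained on all
    trials; strength windows default to the full train/test windows."""
    labels = np.asarray(labels).astype(bool)
    groups = {"low": assignment.low, "high": assignment.high}
    for name, g in groups.items():
        if labels[g].all() or not labels[g].any():
            raise ValueError(f"bin {name!r} contains a single probe class")
    tg = time_generalization(epochs, labels, train_window, test_window,
                             groups=groups, shrinkage=shrinkage,
                             decode_sfreq=decode_sfreq)
    stw = strength_train_window or train_window
    return {"strength_low": memory_strength(tg["low"], stw, test_window),
            "strength_high": memory_strength(tg["high"], stw, test_window)}


def bin_analysis_subject(epochs: EpochSet, labels: np.ndarray,
                         powers_by_band: dict,
                         train_window: tuple[float, float],
                         test_window: tuple[float, float],
                         strength_train_window: tuple[float, float] | None = None,
                         subject: int = 0, shrinkage="auto",
                         decode_sfreq: float | None = 100.0) -> list[dict]:
    """Per-subject bin analysis for several bands at once.

    All bands share the same probe-trained classifiers (training pools all
    trials), so the time-generalization scores are computed once and only
    the AUC grouping differs per band/bin.  Returns one record per band.
    """
    labels = np.asarray(labels).astype(bool)
    groups = {}
    assignments = {}
    for band, powers in powers_by_band.items():
        a = median_split(powers)
        assignments[band] = a
        groups[f"{band}_low"] = a.low
        groups[f"{band}_high"] = a.high
    tg = time_generalization(epochs, labels, train_window, test_window,
                             groups=groups, shrinkage=shrinkage,
                             decode_sfreq=decode_sfreq)
    stw = strength_train_window or train_window
    records = []
    for band, powers in powers_by_band.items():
        records.append({
            "subject": subject, "band": band,
            "strength_low": memory_strength(tg[f"{band}_low"], stw,
                                            test_window),
            "strength_high": memory_strength(tg[f"{band}_high"], stw,
                                             test_window),
            "modulation": modulation_ratio(powers, assignments[band]),
        })
    return records


@dataclass
class BinDecodingSummary:
    """One row per subject x band."""
    frame: pd.DataFrame          # subject, band, strength_low, strength_high,
                                 # diff (low - high), modulation

    @classmethod
    def from_records(cls, records: list[dict]) -> "BinDecodingSummary":
        df = pd.DataFrame.from_records(records)
        df["diff"] = df["strength_low"] - df["strength_high"]
        return cls(frame=df)

    def band(self, name: str) -> pd.DataFrame:
        return self.frame[self.frame["band"] == name].sort_values("subject")

    def anova_table(self, bands=("alpha", "beta")) -> np.ndarray:
        """(n_subjects, 2 bands, 2 bins) strength table for the RM-ANOVA;
        bin order (low, high)."""
        subjects = sorted(self.frame["subject"].unique())
        out = np.empty((len(subjects), len(bands), 2))
        for si, s in enumerate(subjects):
            for bi, b in enumerate(bands):
                row = self.frame[(self.frame.subject == s)
                                 & (self.frame.band == b)]
                if len(row) != 1:
                    raise ValueError("incomplete subject x band table")
                out[si, bi, 0] = row["strength_low"].iloc[0]
                out[si, bi, 1] = row["strength_high"].iloc[0]
        return out


def modulation_strength_correlation(summary: BinDecodingSummary, band: str
                                    ) -> tuple[float, float]:
    """Pearson r (and two-sided p) between the power-modulation ratio M and
    the high-minus-low strength difference across subjects."""
    df = summary.band(band)
    if len(df) < 3:
        raise ValueError("need at least three subjects")
    m = df["modulation"].to_numpy()
    diff_high_minus_low = -df["diff"].to_numpy()
    return pearson(m, diff_high_minus_low)
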