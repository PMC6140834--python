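"""Shared containers for the feeding-trial design.

The trial samples two tissues (gut, liver) at four time points (day 0 and
weeks 3, 5, 7).  Consecutive time points define the three *stages* used
throughout the analysis: early (3w vs 0d), middle (5w vs 3w) and late
(7w vs 5w).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TIMEPOINTS: tuple[str, ...] = ("0d", "3w", "5w", "7w")
TISSUES: tuple[str, ...] = ("gut", "liver")

#: stage label -> (reference time point, test time point)
STAGES: dict[str, tuple[str, str]] = {
    "early": ("0d", "3w"),
    "middle": ("3w", "5w"),
    "late": ("5w", "7w"),
}

SAMPLE_SHEET_COLUMNS = ("sample_id", "tissue", "timepoint", "replicate")


@dataclass
class CountMatrix:
    """Integer count matrix (features x samples) with its sample sheet.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, one row per feature, one column per
        sample.  Column order must match ``samples``.
    samples : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``tissue``
        (``gut``/``liver``), ``timepoint`` (``0d``/``3w``/``5w``/``7w``)
        and ``replicate`` (positive integer).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        sids = self.samples["sample_id"].astype(str).tolist()
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample_ids in sample sheet")
        if list(self.counts.columns) != sids:
            raise ValueError("count matrix columns do not match sample sheet order")
        bad_tissue = set(self.samples["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValueError(f"unknown tissue labels: {sorted(bad_tissue)}")
        bad_tp = set(self.samples["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown time points: {sorted(bad_tp)}")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        reps = self.samples.groupby("timepoint", observed=True)["sample_id"].count()
        low = reps[reps < 2]
        if len(low):
            raise ValueError(
                "every time point needs >=2 replicates for testing; "
                f"got {low.to_dict()}"
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def timepoints_present(self) -> list[str]:
        present = set(self.samples["timepoint"])
        return [t for t in TIMEPOINTS if t in present]

    def samples_at(self, timepoint: str) -> list[str]:
        """Sample ids measured at one time point (sheet order)."""
        sel = self.samples["timepoint"] == timepoint
        return self.samples.loc[sel, "sample_id"].astype(str).tolist()

    def subset_tissue(self, tissue: str) -> "CountMatrix":
        sel = self.samples["tissue"] == tissue
        sub = self.samples[sel].reset_index(drop=True)
        return CountMatrix(self.counts[sub["sample_id"].tolist()], sub)

    # --- TSV round trip -------------------------------------------------
    def to_tsv(self, counts_path, samples_path) -> None:
        out = self.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t")
        samples["sample_id"] = samples["sample_id"].astype(str)
        counts.columns = [str(c) for c in counts.columns]
        return cls(counts, samples)


def stage_comparison(stage: str) -> tuple[str, str]:
    """Map a stage label to its (reference, test) time-point pair."""
    try:
        return STAGES[stage]
    except KeyError:
        raise KeyError(f"unknown stage {stage!r}; expected one of {sorted(STAGES)}")
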