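"""Growth-performance, organ-index and morphometry statistics.

Implements the standard fish-trial formulas:

    WG%      = 100 * (final - initial) / initial
    SGR      = 100 * (final - initial) / days          (linear form, default)
    SGR(log) = 100 * (ln final - ln initial) / days    (behind log_form=True)
    FE       = 100 * weight gain / feed intake
    ADFI     = feed consumption / fish number / days   (g/day/fish)
    survival = 100 * live fish at end / live fish at start
    HI       = 100 * hepatopancreas weight / body weight
    ILI      = 100 * intestine length / body length
    ISI      = 100 * intestine weight / body weight

plus immunofluorescence mean density (background-corrected per-area
intensity), stained percent area, and Welch group comparisons (alpha 0.05
for growth, 0.01 for morphology).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

GROWTH_ALPHA = 0.05
MORPHOLOGY_ALPHA = 0.01


@dataclass
class GrowthRecord:
    """Per-cage trial record; any field may be None for partial metrics."""

    initial_weight: float | None = None  # g/fish
    final_weight: float | None = None    # g/fish
    feed_consumed: float | None = None   # g
    fish_n_start: int | None = None
    fish_n_end: int | None = None
    days: int | None = None
    body_weight: float | None = None     # g
    body_length: float | None = None     # cm
    hepatopancreas_weight: float | None = None  # g
    intestine_weight: float | None = None       # g
    intestine_length: float | None = None       # cm

    def __post_init__(self) -> None:
        for name in ("initial_weight", "final_weight", "body_weight", "body_length",
                     "hepatopancreas_weight", "intestine_weight", "intestine_length"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive; got {v}")
        if self.days is not None and self.days < 1:
            raise ValueError("days must be >= 1")
        if (
            self.fish_n_start is not None
            and self.fish_n_end is not None
            and self.fish_n_end > self.fish_n_start
        ):
            raise ValueError("fish_n_end cannot exceed fish_n_start")


def growth_metrics(rec: GrowthRecord, log_form_sgr: bool = False) -> dict[str, float]:
    """All growth/organ metrics computable from a (possibly partial) record.

    Returns a dict with keys among WG_pct, SGR, FE, ADFI, survival_pct,
    HI, ILI, ISI; metrics whose inputs are missing are omitted.
    """
    out: dict[str, float] = {}
    r = rec
    if r.initial_weight is not None and r.final_weight is not None:
        out["WG_pct"] = 100.0 * (r.final_weight - r.initial_weight) / r.initial_weight
        if r.days is not None:
            if log_form_sgr:
                out["SGR"] = 100.0 * (np.log(r.final_weight) - np.log(r.initial_weight)) / r.days
            else:
                out["SGR"] = 100.0 * (r.final_weight - r.initial_weight) / r.days
        if r.feed_consumed is not None:
            if r.feed_consumed == 0:
                raise ZeroDivisionError("feed_consumed is zero; FE undefined")
            # weights are g/fish while feed_consumed is the cage total, so
            # feed is put on a per-fish basis when the stocking count is known
            per_fish_feed = (
                r.feed_consumed / r.fish_n_start
                if r.fish_n_start else r.feed_consumed
            )
            out["FE"] = 100.0 * (r.final_weight - r.initial_weight) / per_fish_feed
    if r.feed_consumed is not None and r.fish_n_start is not None and r.days is not None:
        if r.fish_n_start == 0:
            raise ZeroDivisionError("fish_n_start is zero; ADFI undefined")
        out["ADFI"] = r.feed_consumed / r.fish_n_start / r.days
    if r.fish_n_start is not None and r.fish_n_end is not None:
        if r.fish_n_start == 0:
            raise ZeroDivisionError("fish_n_start is zero; survival undefined")
        out["survival_pct"] = 100.0 * r.fish_n_end / r.fish_n_start
    if r.hepatopancreas_weight is not None and r.body_weight is not None:
        out["HI"] = 100.0 * r.hepatopancreas_weight / r.body_weight
    if r.intestine_length is not None and r.body_length is not None:
        out["ILI"] = 100.0 * r.intestine_length / r.body_length
    if r.intestine_weight is not None and r.body_weight is not None:
        out["ISI"] = 100.0 * r.intestine_weight / r.body_weight
    return out


@dataclass
class DensityInput:
    """Immunofluorescence image with signal mask and background regions."""

    intensity: np.ndarray           # non-negative, 2-D
    signal_mask: np.ndarray         # boolean, same shape
    background_rois: list[np.ndarray]  # boolean masks, same shape

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.signal_mask = np.asarray(self.signal_mask, dtype=bool)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2-D")
        if (self.intensity < 0).any():
            raise ValueError("intensity must be non-negative")
        if self.signal_mask.shape != self.intensity.shape:
            raise ValueError("signal mask shape mismatch")
        if not self.background_rois:
            raise ValueError("need >=1 background roi")
        self.background_rois = [np.asarray(m, dtype=bool) for m in self.background_rois]
        for i, m in enumerate(self.background_rois):
            if m.shape != self.intensity.shape:
                raise ValueError(f"background roi {i} shape mismatch")
            if not m.any():
                raise ValueError(f"background roi {i} is empty")
            if (m & self.signal_mask).any():
                log.info("background roi %d overlaps the signal mask", i)


def mean_density(inp: DensityInput) -> float:
    """Background-corrected per-area signal intensity.

    mean density = (sum of signal intensities
                    - mean background density * signal area) / image area,
    where the background density is the mean over ROIs of (ROI intensity
    sum / ROI area).  An empty signal mask yields 0.
    """
    if not inp.signal_mask.any():
        log.info("empty signal mask; mean density 0")
        return 0.0
    int_den = float(inp.intensity[inp.signal_mask].sum())
    bg = float(
        np.mean([inp.intensity[m].sum() / m.sum() for m in inp.background_rois])
    )
    signal_area = int(inp.signal_mask.sum())
    return (int_den - bg * signal_area) / inp.intensity.size


def percent_area(mask) -> float:
    """Percentage of true pixels (e.g. oil-red stained area)."""
    arr = np.asarray(mask, dtype=bool)
    if arr.size == 0:
        raise ValueError("mask is empty")
    return 100.0 * arr.sum() / arr.size


def group_compare(values_a, values_b, alpha: float) -> dict:
    """Two-sided Welch t-test between groups with a significance flag."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return {"p": p, "significant": p < alpha, "alpha": alpha}
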