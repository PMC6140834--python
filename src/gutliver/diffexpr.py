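"""Stage-wise negative-binomial differential expression.

Counts are normalised with median-of-ratios size factors, per-feature NB
dispersions are estimated by method of moments pooled within groups, and
each consecutive-time-point contrast (early: 3w vs 0d, middle: 5w vs 3w,
late: 7w vs 5w) is tested with a Wald statistic on the log2 fold change
of normalised group means.  P-values are Benjamini-Hochberg adjusted
within each contrast and features are called differentially expressed at
adjusted P < 0.05 by default.

Model
-----
Counts K_ij ~ NB(mu_i * s_j, alpha_i) with Var = mu + alpha * mu^2.  The
log2 fold change uses a pseudocount c = 0.5 on normalised means,

    log2FC = log2((mean_B + c) / (mean_A + c)),

its standard error follows from the NB variance of the group means by the
delta method, and the two-sided p-value refers the Wald statistic
log2FC / SE to the standard normal.

With the very small group sizes of the design (n = 3 mRNA, n = 2 miRNA
per time point) a per-feature dispersion estimate is far too noisy to
plug into the Wald statistic directly, so the stage-wise pipeline shares
dispersion information across features: a robust parametric trend
alpha(mu) = a0 + a1/mu is fitted to the per-feature method-of-moments
estimates and each feature is tested with the *larger* of its own
estimate and the trend value.  This mirrors the conservative handling of
dispersion outliers in standard NB differential-expression engines and
keeps the null type-I error close to nominal at n = 3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import STAGES, TIMEPOINTS, CountMatrix, stage_comparison

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


def size_factors(counts, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Parameters
    ----------
    counts : array-like or DataFrame, features x samples
    pseudo_reference : bool
        If no feature has all-positive counts, fall back to a reference
        built from features expressed in at least half the samples
        (geometric mean over their positive entries).  Off by default.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] == 0:
        raise ValueError("counts must be a 2-D features x samples array")
    zero_free = (arr > 0).all(axis=1)
    if zero_free.any():
        with np.errstate(divide="ignore"):
            logref = np.log(arr[zero_free]).mean(axis=1)
        ratios = np.log(arr[zero_free]) - logref[:, None]
    else:
        if not pseudo_reference:
            raise ValueError(
                "no feature has positive counts in every sample; "
                "pass pseudo_reference=True to use a pseudo-reference fallback"
            )
        expressed = (arr > 0).sum(axis=1) >= max(1, arr.shape[1] // 2)
        if not expressed.any():
            raise ValueError("matrix is all zero; size factors undefined")
        sub = arr[expressed]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        logref = np.nanmean(logs, axis=1)
        ratios = np.where(sub > 0, np.log(sub) - logref[:, None], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        logsf = np.nanmedian(ratios, axis=0)
    logsf = logsf - logsf.mean()  # geometric mean 1
    return np.exp(logsf)


def estimate_dispersion(
    norm_counts, groups: list[np.ndarray], floor: float = DISPERSION_FLOOR
) -> np.ndarray:
    """Method-of-moments NB dispersion per feature, pooled within groups.

    ``groups`` lists, per group, the column indices of its replicates.
    Within-group means and variances are pooled across groups; the
    dispersion is max(floor, (s2 - mu) / mu^2).
    """
    arr = np.asarray(norm_counts, dtype=float)
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs >=2 replicates")
    means = np.stack([arr[:, g].mean(axis=1) for g in groups])
    variances = np.stack([arr[:, g].var(axis=1, ddof=1) for g in groups])
    dfs = np.array([len(g) - 1 for g in groups], dtype=float)
    mu = means.mean(axis=0)
    s2 = (variances * dfs[:, None]).sum(axis=0) / dfs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return np.maximum(floor, alpha)


def dispersion_trend(alpha_mom, mu) -> np.ndarray:
    """Robust parametric mean-dispersion trend alpha(mu) = a0 + a1/mu.

    Fitted by iteratively reweighted least squares on the per-feature
    method-of-moments estimates, down-weighting features whose estimate
    exceeds three times the current trend (dispersion outliers).  With
    fewer than 20 usable features the trend degenerates to the median
    estimate.  Returns the trend evaluated at each feature's mean.
    """
    alpha_mom = np.asarray(alpha_mom, dtype=float)
    mu = np.asarray(mu, dtype=float)
    keep = mu > 1
    if keep.sum() < 20:
        med = float(np.median(alpha_mom)) if alpha_mom.size else DISPERSION_FLOOR
        return np.full_like(alpha_mom, max(med, DISPERSION_FLOOR))
    x, y = 1.0 / mu[keep], alpha_mom[keep]
    X = np.stack([np.ones(x.size), x], axis=1)
    w = np.ones(x.size, dtype=bool)
    coef = np.array([np.median(y), 0.0])
    for _ in range(5):
        coef, *_ = np.linalg.lstsq(X[w], y[w], rcond=None)
        pred = np.maximum(X @ coef, DISPERSION_FLOOR)
        w = y < 3.0 * pred
        if w.sum() < 20:
            break
    a0, a1 = max(coef[0], DISPERSION_FLOOR), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-8)
    return np.maximum(trend, DISPERSION_FLOOR)


def nb_wald(
    counts_a,
    counts_b,
    sf_a,
    sf_b,
    dispersion,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """NB Wald test of group B vs group A per feature.

    Returns a DataFrame with columns ``log2FC``, ``SE``, ``p`` and
    ``all_zero`` (features with zero counts in both groups, reported with
    log2FC = 0 and p = 1).  Raw count blocks are normalised by their size
    factors before group means are formed.
    """
    a = np.asarray(counts_a, dtype=float) / np.asarray(sf_a, dtype=float)
    b = np.asarray(counts_b, dtype=float) / np.asarray(sf_b, dtype=float)
    na, nb_ = a.shape[1], b.shape[1]
    if na == 0 or nb_ == 0:
        raise ValueError("both groups must be non-empty")
    disp = np.asarray(dispersion, dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    # delta method on log2(mean + c); NB variance of the normalised mean
    var_a = (mean_a + disp * mean_a**2) / na
    var_b = (mean_b + disp * mean_b**2) / nb_
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_a / ((mean_a + pseudocount) * ln2) ** 2
        + var_b / ((mean_b + pseudocount) * ln2) ** 2
    )
    all_zero = (mean_a == 0) & (mean_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)
    return pd.DataFrame(
        {"log2FC": log2fc, "SE": se, "p": np.clip(p, 0.0, 1.0), "all_zero": all_zero}
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass
class StageDEResult:
    """Per-contrast differential expression table with up/down calls."""

    comparison: str
    ref_timepoint: str
    test_timepoint: str
    table: pd.DataFrame  # index feature_id; log2FC, SE, p, padj, call
    alpha: float = 0.05

    @property
    def up_set(self) -> list[str]:
        return self.table.index[self.table["call"] == "up"].tolist()

    @property
    def down_set(self) -> list[str]:
        return self.table.index[self.table["call"] == "down"].tolist()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def _test_pair(
    cm: CountMatrix,
    sf: pd.Series,
    ref: str,
    test: str,
    label: str,
    alpha: float,
) -> StageDEResult:
    cols_a = cm.samples_at(ref)
    cols_b = cm.samples_at(test)
    a_raw = cm.counts[cols_a].to_numpy(dtype=float)
    b_raw = cm.counts[cols_b].to_numpy(dtype=float)
    keep = ~((a_raw.sum(axis=1) == 0) & (b_raw.sum(axis=1) == 0))
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("%s: excluding %d all-zero features before testing", label, n_dropped)
    sf_a = sf[cols_a].to_numpy()
    sf_b = sf[cols_b].to_numpy()
    a = a_raw[keep] / sf_a
    b = b_raw[keep] / sf_b
    mom = estimate_dispersion(
        np.concatenate([a, b], axis=1),
        [np.arange(len(cols_a)), np.arange(len(cols_a), len(cols_a) + len(cols_b))],
    )
    mu = np.concatenate([a, b], axis=1).mean(axis=1)
    disp = np.maximum(mom, dispersion_trend(mom, mu))
    res = nb_wald(a_raw[keep], b_raw[keep], sf_a, sf_b, disp)
    res.index = cm.feature_ids[keep]
    # deterministic BH: stable order by (p, feature id)
    order = np.lexsort((res.index.astype(str), res["p"].to_numpy()))
    padj = np.empty(len(res))
    padj[order] = bh_adjust(res["p"].to_numpy()[order])
    res["padj"] = padj
    call = np.where(
        (res["padj"] < alpha) & (res["log2FC"] > 0),
        "up",
        np.where((res["padj"] < alpha) & (res["log2FC"] < 0), "down", "ns"),
    )
    res["call"] = call
    res = res.drop(columns="all_zero")
    return StageDEResult(label, ref, test, res, alpha)


def stage_de(
    cm: CountMatrix,
    alpha: float = 0.05,
    extra_comparisons: list[tuple[str, str]] | None = None,
) -> dict[str, StageDEResult]:
    """Differential expression for the three consecutive-stage contrasts.

    ``extra_comparisons`` adds arbitrary (ref, test) time-point pairs
    (keyed ``"<test>_vs_<ref>"``), e.g. for time-point-specific tallies.
    Requires all four canonical time points; BH correction is applied
    within each contrast across all features that are not all-zero there.
    """
    present = cm.timepoints_present
    missing = [t for t in TIMEPOINTS if t not in present]
    if missing:
        raise ValueError(
            f"missing time points {missing}; available: {present}"
        )
    n_reps = cm.samples.groupby("timepoint", observed=True)["sample_id"].count()
    if (n_reps == 2).any():
        warnings.warn(
            "only 2 replicates at some time points; statistical power is minimal",
            UserWarning,
            stacklevel=2,
        )
    sf = pd.Series(
        size_factors(cm.counts.to_numpy(), pseudo_reference=True),
        index=cm.counts.columns,
    )
    results: dict[str, StageDEResult] = {}
    for stage in STAGES:
        ref, test = stage_comparison(stage)
        results[stage] = _test_pair(cm, sf, ref, test, stage, alpha)
    for ref, test in extra_comparisons or []:
        label = f"{test}_vs_{ref}"
        results[label] = _test_pair(cm, sf, ref, test, label, alpha)
    return results


class StageDEModel:
    """Stage-wise NB differential expression model for one tissue.

    Thin statsmodels-style front end: construct from a :class:`CountMatrix`
    (optionally restricted to one tissue), then :meth:`fit` to obtain a
    :class:`StageDEResults` carrying per-stage tables, up/down sets and a
    summary.
    """

    def __init__(self, data: CountMatrix, tissue: str | None = None, alpha: float = 0.05):
        self.data = data.subset_tissue(tissue) if tissue else data
        self.tissue = tissue
        self.alpha = alpha

    @classmethod
    def from_tsv(cls, counts_path, samples_path, **kwargs) -> "StageDEModel":
        return cls(CountMatrix.from_tsv(counts_path, samples_path), **kwargs)

    def fit(self, extra_comparisons=None) -> "StageDEResults":
        res = stage_de(self.data, self.alpha, extra_comparisons)
        return StageDEResults(self, res)


@dataclass
class StageDEResults:
    """Fitted stage-wise DE results; ``results`` maps stage -> StageDEResult."""

    model: StageDEModel
    results: dict[str, StageDEResult] = field(default_factory=dict)

    def __getitem__(self, stage: str) -> StageDEResult:
        return self.results[stage]

    def summary(self) -> pd.DataFrame:
        rows = []
        for stage, r in self.results.items():
            rows.append(
                {
                    "comparison": stage,
                    "contrast": f"{r.test_timepoint} vs {r.ref_timepoint}",
                    "n_tested": len(r.table),
                    "n_up": len(r.up_set),
                    "n_down": len(r.down_set),
                    "alpha": r.alpha,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv_dir(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for stage, r in self.results.items():
            r.to_tsv(outdir / f"de_{stage}.tsv")
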