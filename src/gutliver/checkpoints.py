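"""Immune-checkpoint selection from category-level time-course tests.

Member genes of each immune (process, category) bucket are aggregated to a
per-sample mean of log2(normalised count + 1); Welch t-tests compare the
aggregate between time points, BH-adjusted across categories within each
comparison.  A category is selected as an immune checkpoint of homeostasis
when its significance pattern indicates restored (gut) or altered (liver)
homeostasis:

* gut rule — significantly different between 7w and 5w (or 3w) but NOT
  significantly different between 7w and 0d (perturbed, then restored to
  baseline);
* liver rule — significantly different between 0d and 3w (or 5w, or 7w).

Significance inside the rules uses BH-adjusted p < alpha by default; a
raw-p mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix
from .diffexpr import bh_adjust, size_factors
from .immune_library import ImmuneGeneLibrary

log = logging.getLogger(__name__)

GUT_COMPARISONS = [("5w", "7w"), ("3w", "7w"), ("0d", "7w")]
LIVER_COMPARISONS = [("0d", "3w"), ("0d", "5w"), ("0d", "7w")]


def _comparison_label(a: str, b: str) -> str:
    return f"{b}_vs_{a}"


@dataclass
class CategoryProfile:
    """Per-(process, category) per-sample mean log2 normalised expression."""

    values: pd.DataFrame  # MultiIndex (process, category) x samples
    member_counts: pd.Series  # genes per category
    samples: pd.DataFrame  # sample sheet


def category_profile(
    cm: CountMatrix, library: ImmuneGeneLibrary
) -> CategoryProfile:
    """Aggregate member genes to a category-level expression profile.

    For every library (process, category) with at least one expressed
    member gene present in the matrix, the profile is the mean over member
    genes of log2(normalised count + 1) per sample.  Categories with no
    expressed members are dropped with a log entry.
    """
    sf = size_factors(cm.counts.to_numpy(), pseudo_reference=True)
    norm = cm.counts.to_numpy(dtype=float) / sf
    logexpr = pd.DataFrame(
        np.log2(norm + 1.0), index=cm.feature_ids, columns=cm.counts.columns
    )
    members: dict[tuple[str, str], list[str]] = {}
    present = set(cm.feature_ids)
    for g, p, c in library.records:
        if g in present:
            members.setdefault((p, c), []).append(g)
    dropped = len({(p, c) for _, p, c in library.records}) - len(members)
    if dropped:
        log.info("dropped %d categories with no expressed member genes", dropped)
    if not members:
        raise ValueError("no library category has expressed member genes")
    rows, counts = {}, {}
    for key, genes in members.items():
        expressed = logexpr.loc[genes]
        rows[key] = expressed.mean(axis=0)
        counts[key] = len(genes)
    values = pd.DataFrame(rows).T
    values.index = pd.MultiIndex.from_tuples(values.index, names=["process", "category"])
    return CategoryProfile(values, pd.Series(counts), cm.samples)


def category_tests(
    profile: CategoryProfile,
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per category for each (ref, test) time-point pair.

    Returns a long DataFrame (process, category, comparison, p, padj,
    significant); BH is applied across categories within each comparison.
    Zero variance in both groups with equal means yields p = 1.
    """
    sheet = profile.samples
    out = []
    for ref, test in comparisons:
        a_cols = sheet.loc[sheet["timepoint"] == ref, "sample_id"].tolist()
        b_cols = sheet.loc[sheet["timepoint"] == test, "sample_id"].tolist()
        if len(a_cols) < 2 or len(b_cols) < 2:
            raise ValueError(f"comparison {test} vs {ref} needs >=2 replicates per side")
        a = profile.values[a_cols].to_numpy()
        b = profile.values[b_cols].to_numpy()
        ps = np.ones(len(profile.values))
        for i in range(len(ps)):
            if np.ptp(a[i]) == 0 and np.ptp(b[i]) == 0:
                ps[i] = 1.0 if a[i, 0] == b[i, 0] else 0.0
            else:
                ps[i] = stats.ttest_ind(a[i], b[i], equal_var=False).pvalue
        padj = bh_adjust(ps)
        label = _comparison_label(ref, test)
        for (proc, cat), p, q in zip(profile.values.index, ps, padj):
            out.append(
                {
                    "process": proc,
                    "category": cat,
                    "comparison": label,
                    "p": p,
                    "padj": q,
                    "significant": q < alpha,
                }
            )
    return pd.DataFrame(out)


def select_checkpoints(
    tests: pd.DataFrame,
    tissue: str,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Apply the tissue-specific checkpoint rule to category test results.

    gut: selected iff significant in 7w vs 5w OR 7w vs 3w, AND NOT
    significant in 7w vs 0d.  liver: selected iff significant in any of
    3w/5w/7w vs 0d.  Returns one row per category with per-comparison
    p/padj columns, ``selected`` and a ``rule_trace`` naming the clauses
    that fired.
    """
    needed = GUT_COMPARISONS if tissue == "gut" else LIVER_COMPARISONS
    labels = [_comparison_label(a, b) for a, b in needed]
    have = set(tests["comparison"])
    missing = [l for l in labels if l not in have]
    if missing:
        raise ValueError(f"missing required comparisons for {tissue}: {missing}")
    col = "padj" if use_adjusted else "p"
    wide_p = tests.pivot_table(
        index=["process", "category"], columns="comparison", values="p"
    )
    wide_q = tests.pivot_table(
        index=["process", "category"], columns="comparison", values="padj"
    )
    sig = tests.pivot_table(
        index=["process", "category"], columns="comparison", values=col
    ) < alpha
    rows = []
    for key in wide_p.index:
        proc, cat = key
        trace = []
        if tissue == "gut":
            restored = not sig.loc[key, "7w_vs_0d"]
            perturbed = False
            for lbl in ("7w_vs_5w", "7w_vs_3w"):
                if sig.loc[key, lbl]:
                    perturbed = True
                    trace.append(f"sig:{lbl}")
            if restored:
                trace.append("ns:7w_vs_0d")
            selected = perturbed and restored
        else:
            selected = False
            for lbl in labels:
                if sig.loc[key, lbl]:
                    selected = True
                    trace.append(f"sig:{lbl}")
        row = {"tissue": tissue, "process": proc, "category": cat}
        for lbl in labels:
            row[f"p_{lbl}"] = wide_p.loc[key, lbl]
            row[f"padj_{lbl}"] = wide_q.loc[key, lbl]
        row["selected"] = bool(selected)
        row["rule_trace"] = ";".join(trace) if selected else ""
        rows.append(row)
    return pd.DataFrame(rows)


def checkpoint_table(
    cm: CountMatrix,
    library: ImmuneGeneLibrary,
    tissue: str,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """End-to-end checkpoint derivation for one tissue's count matrix.

    Output mirrors the published checkpoint table layout: tissue, immune
    process, immune category, member gene ids, per-comparison p/padj,
    selection flag and rule trace.
    """
    profile = category_profile(cm, library)
    comparisons = GUT_COMPARISONS if tissue == "gut" else LIVER_COMPARISONS
    tests = category_tests(profile, comparisons, alpha)
    table = select_checkpoints(tests, tissue, alpha, use_adjusted)
    present = set(cm.feature_ids)
    member_map = {}
    for g, p, c in library.records:
        if g in present:
            member_map.setdefault((p, c), []).append(g)
    table.insert(
        3,
        "member_gene_ids",
        [",".join(member_map.get((r.process, r.category), [])) for r in table.itertuples()],
    )
    return table
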