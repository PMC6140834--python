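"""Gene-set over-representation with rich factors and BH q-values.

For each supplied gene set the upper-tail hypergeometric probability of
observing at least k differentially expressed members is computed against
the tested universe, q-values are BH-adjusted across the sets queried in
one panel, and the *rich factor* k/K (DE members over set size within the
universe) gives the dot-plot abscissa.  Significance is called at
q < 0.05 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe of tested genes."""

    sets: dict[str, tuple[str, list[str]]]  # set_id -> (name, genes)
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            self.universe = sorted(uni)
        restricted = {}
        for sid, (name, genes) in self.sets.items():
            kept = sorted(set(genes) & uni)
            if kept:
                restricted[sid] = (name, kept)
        dropped = len(self.sets) - len(restricted)
        if dropped:
            log.info("dropped %d gene sets empty after universe restriction", dropped)
        self.sets = restricted

    @classmethod
    def from_gmt(cls, path, universe: list[str]) -> "GeneSetCollection":
        """Read GMT (set_id <TAB> description <TAB> gene...) and restrict."""
        sets: dict[str, tuple[str, list[str]]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
        return cls(sets, universe)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for sid, (name, genes) in self.sets.items():
                fh.write("\t".join([sid, name, *genes]) + "\n")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: set genes in universe, n: DE genes in universe,
    k: DE genes in the set.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    de_genes: list[str],
    collection: GeneSetCollection,
    alpha_q: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``de_genes`` in every set of ``collection``.

    DE genes outside the universe are dropped (logged).  One row per set
    with at least one DE member; BH adjustment across the tested sets;
    rows sorted by q ascending then rich factor descending.
    """
    uni = set(collection.universe)
    de = sorted(set(de_genes) & uni)
    n_out = len(set(de_genes)) - len(de)
    if n_out:
        log.info("dropped %d DE genes outside the universe", n_out)
    N, n = len(uni), len(de)
    rows = []
    de_set = set(de)
    for sid, (name, genes) in collection.sets.items():
        K = len(genes)
        k = len(de_set & set(genes))
        if k < 1:
            continue
        rows.append(
            {
                "set_id": sid,
                "name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "rich_factor": k / K,
                "p": hypergeom_p(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_id", "name", "k", "K", "n", "N", "rich_factor", "p", "q", "significant"]
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha_q
    df = df.sort_values(
        ["q", "rich_factor"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return df
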