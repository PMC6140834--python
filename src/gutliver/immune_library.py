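"""Two-level immune gene library: nine immune processes, free-text categories.

The library maps each gene to one or more (immune process, immune category)
pairs.  The top level is a fixed ontology of nine immune processes spanning
innate and adaptive immunity in teleost fish; the second level is a finer,
free-text immune gene category (e.g. "C3", "C-type lectin").  A gene may
carry several memberships; identical duplicate rows are collapsed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

#: the nine canonical top-level immune processes, in display order
IMMUNE_PROCESSES: tuple[str, ...] = (
    "acute phase reactions",
    "pattern recognition",
    "antigen processing and regulators",
    "complement system",
    "inflammatory cytokines and receptors",
    "adapters, effectors and signal transducers",
    "innate immune cells related",
    "T/B cell antigen activation",
    "other genes related to immune response",
)


def _norm_category(cat: str) -> str:
    # case-insensitive, whitespace-normalised category key
    return re.sub(r"\s+", " ", cat.strip()).lower()


class LibraryValidationError(ValueError):
    """Raised when a library file violates the two-level schema."""


@dataclass
class ImmuneGeneLibrary:
    """Validated immune gene library.

    ``records`` is a list of (gene_id, process, category) tuples with
    duplicate identical rows (category compared case-insensitively after
    whitespace normalisation) collapsed.
    """

    records: list[tuple[str, str, str]]
    process_labels: tuple[str, ...] = field(default=IMMUNE_PROCESSES)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        collapsed: list[tuple[str, str, str]] = []
        for i, (gene, process, category) in enumerate(self.records):
            if not gene or not str(gene).strip():
                raise LibraryValidationError(f"empty gene_id in record {i}")
            if process not in self.process_labels:
                raise LibraryValidationError(
                    f"record {i} ({gene!r}): unknown immune process {process!r}"
                )
            key = (gene, process, _norm_category(category))
            if key in seen:
                continue
            seen.add(key)
            collapsed.append((gene, process, category))
        self.records = collapsed

    @property
    def genes(self) -> set[str]:
        return {g for g, _, _ in self.records}

    @property
    def processes_present(self) -> list[str]:
        present = {p for _, p, _ in self.records}
        return [p for p in self.process_labels if p in present]

    def memberships(self, gene_id: str) -> list[tuple[str, str]]:
        return [(p, c) for g, p, c in self.records if g == gene_id]

    def process_tally(self) -> dict[str, int]:
        """Membership counts per immune process (counting multiplicity)."""
        tally = {p: 0 for p in self.process_labels}
        for _, p, _ in self.records:
            tally[p] += 1
        return tally

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.records, columns=["gene_id", "process", "category"])
        df.to_csv(path, sep="\t", index=False)


def load_library(path) -> ImmuneGeneLibrary:
    """Load and validate a library TSV (gene_id, process, category).

    Raises
    ------
    LibraryValidationError
        If a row carries an unknown immune-process label or an empty
        gene_id; the error names the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "process", "category"}
    if not required <= set(df.columns):
        raise LibraryValidationError(
            f"library file must have columns {sorted(required)}; got {list(df.columns)}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        gene, process, category = row.gene_id, row.process, row.category
        if not gene.strip():
            raise LibraryValidationError(f"row {i + 1}: empty gene_id")
        if process not in IMMUNE_PROCESSES:
            raise LibraryValidationError(
                f"row {i + 1}: unknown immune process {process!r}"
            )
        records.append((gene, process, category))
    lib = ImmuneGeneLibrary(records)
    log.info(
        "loaded immune gene library: %d records, %d genes, per-process %s",
        len(lib.records), len(lib.genes), lib.process_tally(),
    )
    return lib


def classify_genes(
    gene_ids: list[str], library: ImmuneGeneLibrary
) -> tuple[dict[tuple[str, str], list[str]], list[str]]:
    """Partition a gene list by the library's (process, category) buckets.

    Returns ``(partition, non_immune)``.  A gene with several library
    memberships lands in every matching bucket; genes absent from the
    library go only to ``non_immune``.  Input order is preserved within
    each bucket; duplicated input ids are collapsed.
    """
    index: dict[str, list[tuple[str, str]]] = {}
    for g, p, c in library.records:
        index.setdefault(g, []).append((p, c))
    partition: dict[tuple[str, str], list[str]] = {}
    non_immune: list[str] = []
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            continue
        seen.add(g)
        buckets = index.get(g)
        if buckets is None:
            non_immune.append(g)
        else:
            for key in buckets:
                partition.setdefault(key, []).append(g)
    return partition, non_immune
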