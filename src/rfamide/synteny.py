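"""Gene-neighborhood conservation around focal loci.

Neighborhoods are defined by gene order (k genes each side on the focal
scaffold), not base-pair distance, so assemblies of unequal contiguity stay
comparable. Conservation is quantified by shared ortholog count, the Jaccard
index of the two neighborhoods, and the longest collinear run (an LCS over
ortholog-projected gene orders, orientation-agnostic), with an optional
permutation null for the shared count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .precursor import InputError

__all__ = [
    "GeneTable", "OrthologyMap", "NeighborhoodComparison",
    "neighborhood", "compare_neighborhoods", "permutation_null",
]

BED_COLUMNS = ["scaffold", "start", "end", "gene_id", "score", "strand"]


@dataclass
class GeneTable:
    """Ordered gene loci (BED-like): scaffold, start, end, gene_id, score, strand."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BED_COLUMNS if c not in self.df.columns]
        if missing:
            raise InputError(f"gene table missing columns {missing}")
        if self.df["gene_id"].duplicated().any():
            dups = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].tolist()
            raise InputError(f"duplicate gene ids {dups[:5]}")
        if (self.df["start"] >= self.df["end"]).any():
            raise InputError("gene with start >= end")

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneTable":
        df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS,
                         comment="#")
        return cls(df)

    def to_bed(self, path: str | Path) -> None:
        self.df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class OrthologyMap:
    """Cross-genome ortholog pairs (A-gene, B-gene); may be many-to-many."""

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologyMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"],
                         comment="#")
        return cls(frozenset(zip(df["a"], df["b"])))

    @property
    def many_to_many(self) -> bool:
        a_seen, b_seen = set(), set()
        a_dup = b_dup = False
        for a, b in self.pairs:
            a_dup |= a in a_seen
            b_dup |= b in b_seen
            a_seen.add(a)
            b_seen.add(b)
        return a_dup or b_dup

    def partners_of(self, gene: str) -> set[str]:
        return {b for a, b in self.pairs if a == gene}

    def transpose(self) -> "OrthologyMap":
        return OrthologyMap(frozenset((b, a) for a, b in self.pairs))


@dataclass
class NeighborhoodComparison:
    focal_a: str
    focal_b: str
    k: int
    shared_count: int
    jaccard: float
    max_collinear_run: int
    n_a: int
    n_b: int


def neighborhood(table: GeneTable, focal_gene: str, k: int) -> list[str]:
    """Up to k genes either side of the focal gene on its scaffold, by start.

    The focal gene itself is excluded; the window truncates at scaffold ends.
    """
    df = table.df
    row = df[df["gene_id"] == focal_gene]
    if row.empty:
        raise InputError(f"gene {focal_gene!r} not in table")
    scaffold = row.iloc[0]["scaffold"]
    on_scaf = df[df["scaffold"] == scaffold].sort_values("start").reset_index(drop=True)
    idx = on_scaf.index[on_scaf["gene_id"] == focal_gene][0]
    lo = max(0, idx - k)
    genes = on_scaf.iloc[lo:idx + k + 1]["gene_id"].tolist()
    genes.remove(focal_gene)
    return genes


def _lcs(seq_a: list[str], seq_b: list[str], match) -> int:
    na, nb = len(seq_a), len(seq_b)
    dp = np.zeros((na + 1, nb + 1), dtype=int)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            if match(seq_a[i - 1], seq_b[j - 1]):
                dp[i, j] = dp[i - 1, j - 1] + 1
            else:
                dp[i, j] = max(dp[i - 1, j], dp[i, j - 1])
    return int(dp[na, nb])


def compare_neighborhoods(
    nb_a: list[str],
    nb_b: list[str],
    orthology: OrthologyMap,
    focal_a: str = "",
    focal_b: str = "",
    k: int = 0,
) -> NeighborhoodComparison:
    """Shared ortholog count, Jaccard index, and longest collinear run.

    A gene counts as shared once regardless of how many orthologs it has in
    the other window (set semantics; avoids double-counting tandem arrays).
    Collinearity is the LCS of the two gene orders under the ortholog
    relation, maximised over B read forward and reversed (strand-agnostic).
    """
    b_set = set(nb_b)
    pair_lookup = {}
    for a, b in orthology.pairs:
        pair_lookup.setdefault(a, set()).add(b)
    shared = sum(1 for g in nb_a if pair_lookup.get(g, set()) & b_set)
    union = len(nb_a) + len(nb_b) - shared
    jaccard = shared / union if union else 0.0

    def match(a: str, b: str) -> bool:
        return b in pair_lookup.get(a, ())

    run = max(_lcs(nb_a, nb_b, match), _lcs(nb_a, nb_b[::-1], match))
    return NeighborhoodComparison(
        focal_a=focal_a, focal_b=focal_b, k=k,
        shared_count=shared, jaccard=jaccard, max_collinear_run=run,
        n_a=len(nb_a), n_b=len(nb_b),
    )


def permutation_null(
    table_a: GeneTable,
    table_b: GeneTable,
    orthology: OrthologyMap,
    focal_a: str,
    focal_b: str,
    k: int,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[NeighborhoodComparison, float]:
    """Empirical p-value for the observed shared count.

    Null: the B focal gene is replaced by a uniformly random gene of table B
    and the shared count recomputed; p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    nb_a = neighborhood(table_a, focal_a, k)
    obs = compare_neighborhoods(nb_a, neighborhood(table_b, focal_b, k),
                                orthology, focal_a, focal_b, k)
    rng = np.random.default_rng(seed)
    genes_b = table_b.df["gene_id"].tolist()
    exceed = 0
    for _ in range(n_perm):
        fake = genes_b[rng.integers(len(genes_b))]
        null = compare_neighborhoods(nb_a, neighborhood(table_b, fake, k),
                                     orthology)
        if null.shared_count >= obs.shared_count:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return obs, p
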