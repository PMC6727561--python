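"""Gene-set enrichment by the right-tailed Fisher exact (hypergeometric) test.

A differential-expression gene list is tested against user-supplied gene
sets (GMT format) using the panel's endogenous query genes as the reference
universe, which corrects for the sampling bias of a targeted panel: only
genes that could have been detected count toward the margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "read_gene_sets",
    "fisher_right_tail",
    "enrich_sets",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with a free-text source description."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentRow:
    """One gene set's overlap statistics against the reference universe."""

    name: str
    k: int  # overlap count
    K: int  # set size within reference
    n: int  # DE list size within reference
    N: int  # reference size
    p: float

    @property
    def overlap_percent(self) -> float:
        return round(100.0 * self.k / self.K, 1)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then symbols."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"GMT line {lineno} has {len(fields)} fields; need >=3")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        genes = frozenset(g for g in fields[2:] if g)
        sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def fisher_right_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The probability that a random n-gene draw from an N-gene universe with K
    marked genes contains at least k marked genes (upper-tail Fisher exact).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # hypergeom.sf computes the tail via stable log-space summation
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_sets(de_genes: set[str], sets: GeneSetCollection,
                reference: set[str], alpha: float = 0.05,
                ) -> list[EnrichmentRow]:
    """Test every gene set; return rows with p < alpha sorted by p.

    DE genes outside the reference are dropped with a warning; gene sets are
    intersected with the reference to get the in-universe set size K. Ties in
    p break by set name for a deterministic order.
    """
    if not reference:
        raise ValueError("reference gene universe is empty")
    stray = sorted(set(de_genes) - set(reference))
    if stray:
        warnings.warn(
            f"{len(stray)} DE genes outside reference dropped: {stray[:10]}",
            stacklevel=2)
    de = set(de_genes) & set(reference)
    N, n = len(reference), len(de)
    rows: list[EnrichmentRow] = []
    for name in sorted(sets.sets):
        in_ref = sets.sets[name] & set(reference)
        K = len(in_ref)
        if K == 0:
            continue
        k = len(in_ref & de)
        p = fisher_right_tail(k, K, n, N)
        if p < alpha:
            rows.append(EnrichmentRow(name=name, k=k, K=K, n=n, N=N, p=p))
    rows.sort(key=lambda r: (r.p, r.name))
    return rows
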