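"""Over-representation analysis (ORA) per condition, regulation and library.

The test is the one-sided hypergeometric upper tail P(X >= k) — equivalent to
a one-sided Fisher exact test — for an overlap of k genes between a query of
size n and a term of size K drawn from a background universe of size N. Raw
p-values are Benjamini–Hochberg adjusted per (library x condition x
regulation) stratum, i.e. each enrichment run is its own test family, before
significance and top-N filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DomainError, InputError
from .io import ConditionGeneList, GeneSetLibrary

logger = logging.getLogger(__name__)

Regulation = Literal["all", "up", "down"]


@dataclass(frozen=True)
class EnrichmentHit:
    """One (term, database, condition, regulation) enrichment result."""

    term: str
    database: str
    condition: str
    regulation: Regulation
    overlap_genes: frozenset[str]
    k: int  # overlap count
    n: int  # query size (after background restriction)
    K: int  # term size within background
    N: int  # background size
    p_raw: float
    p_adj: float
    rank: int | None = None

    def __post_init__(self):
        if self.k != len(self.overlap_genes):
            raise DomainError("k must equal |overlap_genes|")
        if not (self.k <= min(self.n, self.K) and self.K <= self.N and self.n <= self.N):
            raise DomainError(
                f"infeasible contingency (k={self.k}, n={self.n}, K={self.K}, N={self.N})"
            )
        if self.p_adj < self.p_raw - 1e-15:
            raise DomainError("adjusted p-value cannot be below the raw p-value")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.term, self.database, self.condition, self.regulation)


@dataclass
class EnrichmentTable:
    """Aggregated enrichment hits plus the parameters that produced them."""

    hits: list[EnrichmentHit]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        seen: set[tuple] = set()
        dups: list[tuple] = []
        for h in self.hits:
            if h.key in seen:
                dups.append(h.key)
            seen.add(h.key)
        if dups:
            raise InputError(
                f"duplicate (term, database, condition, regulation) keys: {dups[:3]}"
            )

    def __len__(self) -> int:
        return len(self.hits)


def split_by_regulation(
    cgl: ConditionGeneList, logfc_threshold: float
) -> tuple[ConditionGeneList, ConditionGeneList]:
    """Split a condition's genes into up- and downregulated sublists.

    Genes with log2FC >= +threshold go up, <= -threshold go down; genes
    strictly inside the open band (-t, +t) are dropped (their count is
    logged). A tie at threshold 0 is assigned up.
    """
    missing = set(cgl.genes) - set(cgl.log2fc_map)
    if missing:
        raise InputError(
            f"condition {cgl.condition!r}: {len(missing)} genes lack log2FC "
            f"values (e.g. {sorted(missing)[:5]})"
        )
    up, down, dropped = {}, {}, 0
    for gene in cgl.genes:
        lfc = cgl.log2fc_map[gene]
        if lfc >= logfc_threshold:
            up[gene] = lfc
        elif lfc <= -logfc_threshold:
            down[gene] = lfc
        else:
            dropped += 1
    if dropped:
        logger.info(
            "condition %r: %d genes inside (-%g, %g) dropped from regulation split",
            cgl.condition, logfc_threshold, logfc_threshold, dropped,
        )
    def make(genes: dict) -> ConditionGeneList | None:
        if not genes:
            return None
        return ConditionGeneList(
            condition=cgl.condition, genes=frozenset(genes), log2fc_map=dict(genes)
        )
    return make(up), make(down)


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts white balls in n draws without replacement from an urn of N
    balls of which K are white. Returns a value in (0, 1].
    """
    if N < 1 or not (0 <= k <= min(n, K)) or k < max(0, n + K - N) or K > N or n > N:
        raise DomainError(f"infeasible (k={k}, n={n}, K={K}, N={N})")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-aligned with input."""
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        return ps
    if np.any(ps <= 0) or np.any(ps > 1) or np.any(~np.isfinite(ps)):
        raise DomainError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(ps, method="fdr_bh")
    return adj


def adjust_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    ps = np.asarray(p_values, dtype=float)
    if np.any(ps <= 0) or np.any(ps > 1):
        raise DomainError("p-values must lie in (0, 1]")
    return np.minimum(ps * ps.size, 1.0)


_ADJUSTERS = {"bh": adjust_bh, "bonferroni": adjust_bonferroni}


def enrich_condition(
    genes: Iterable[str],
    library: GeneSetLibrary,
    min_genes: int = 1,
    condition: str = "query",
    regulation: Regulation = "all",
    adjust: str = "bh",
) -> list[EnrichmentHit]:
    """Test every overlapping library term against one query gene list.

    The query is restricted to the library background first (the number of
    unmatched genes is logged). The BH family comprises all tested terms —
    every term with overlap k >= 1 — and the ``min_genes`` size filter is
    applied only afterwards, so adjusted p-values do not depend on it.
    """
    if adjust not in _ADJUSTERS:
        raise ConfigurationError(f"unknown adjustment method {adjust!r}")
    query = frozenset(genes)
    if not query:
        raise InputError("query gene set is empty")
    restricted = query & library.background
    n_lost = len(query) - len(restricted)
    if n_lost:
        logger.info(
            "condition %r vs %r: %d/%d query genes outside the library background",
            condition, library.name, n_lost, len(query),
        )
    if not restricted:
        raise InputError(
            f"no query genes match the background of library {library.name!r}"
        )
    n, N = len(restricted), len(library.background)
    tested: list[tuple[str, frozenset[str]]] = []
    p_raws: list[float] = []
    for term in sorted(library.sets):
        overlap = restricted & library.sets[term]
        if not overlap:
            continue
        tested.append((term, overlap))
        p_raws.append(hypergeom_pvalue(len(overlap), n, len(library.sets[term]), N))
    if not tested:
        return []
    p_adjs = _ADJUSTERS[adjust](p_raws)
    hits = []
    for (term, overlap), p_raw, p_adj in zip(tested, p_raws, p_adjs):
        if len(overlap) < min_genes:
            continue
        hits.append(
            EnrichmentHit(
                term=term,
                database=library.name,
                condition=condition,
                regulation=regulation,
                overlap_genes=overlap,
                k=len(overlap),
                n=n,
                K=len(library.sets[term]),
                N=N,
                p_raw=p_raw,
                p_adj=float(max(p_adj, p_raw)),
            )
        )
    return hits


def filter_and_rank(
    hits: Sequence[EnrichmentHit],
    padj_max: float = 0.05,
    top_n: int = 5,
) -> list[EnrichmentHit]:
    """Keep the top-N most significant hits per stratum and assign ranks.

    Within each (condition, regulation, database) stratum, hits with
    p_adj < padj_max are sorted by ascending p_adj (ties: larger overlap k
    first, then term name) and the first ``top_n`` get ranks 1..top_n.
    """
    if top_n < 1:
        raise ConfigurationError(f"top_n must be >= 1, got {top_n}")
    strata: dict[tuple, list[EnrichmentHit]] = {}
    for h in hits:
        strata.setdefault((h.condition, h.regulation, h.database), []).append(h)
    out: list[EnrichmentHit] = []
    for stratum_key in sorted(strata):
        kept = [h for h in strata[stratum_key] if h.p_adj < padj_max]
        kept.sort(key=lambda h: (h.p_adj, -h.k, h.term))
        for rank, h in enumerate(kept[:top_n], start=1):
            out.append(replace(h, rank=rank))
    return out


def aggregate_conditions(tables: Sequence[EnrichmentTable]) -> EnrichmentTable:
    """Concatenate enrichment tables across conditions and databases.

    The (term, database, condition, regulation) key must stay unique across
    the union; provenance dictionaries are merged.
    """
    hits: list[EnrichmentHit] = []
    provenance: dict = {}
    for t in tables:
        hits.extend(t.hits)
        provenance.update(t.provenance)
    return EnrichmentTable(hits=hits, provenance=provenance)
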