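"""Per-cluster p-value pooling, annotation handling and coherence scoring.

Each (cluster x condition x regulation) cell pools the adjusted p-values of
its contributing terms into one cluster-level p-value using Fisher's method,
Stouffer's method, a weighted Z-test or the Cauchy combination test. Values
are floored before pooling so the chi-square / probit transforms never see
zero, and the pooled value is capped at the same floor for display. Cluster
coherence is scored as each term's Jaccard similarity against the union of
the other gene sets in its cluster, averaged over multi-term clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .clustering import ClusterAssignment, TermGeneMap, jaccard_similarity
from .enrich import EnrichmentHit
from .exceptions import ConsistencyError, DomainError, FormatError

PoolMethod = Literal["fisher", "stouffer", "weighted_z", "cauchy"]


@dataclass(frozen=True)
class PoolingSpec:
    """How to combine term-level p-values within a cluster.

    ``weights`` selects the weighting rule for weighted_z / cauchy:
    "equal", or "overlap_size" (a term's overlap gene count, so terms backed
    by more query genes carry more evidence). ``floor`` bounds p-values away
    from zero before pooling and caps the pooled value for display.
    """

    method: PoolMethod = "cauchy"
    weights: Literal["equal", "overlap_size"] = "overlap_size"
    floor: float = 1e-10

    def __post_init__(self):
        if self.method not in ("fisher", "stouffer", "weighted_z", "cauchy"):
            raise DomainError(f"unknown pooling method {self.method!r}")
        if not 0 < self.floor < 1:
            raise DomainError(f"floor must lie in (0, 1), got {self.floor}")


def pool_pvalues(
    ps: Sequence[float],
    spec: PoolingSpec | str = "fisher",
    weights: Sequence[float] | None = None,
) -> float:
    """Combine p-values into one with the selected method.

    fisher:      survival of chi2(2k) at -2 * sum(ln p_i)
    stouffer:    upper normal tail at sum(z_i)/sqrt(k), z_i = Phi^-1(1 - p_i)
    weighted_z:  upper normal tail at sum(w_i z_i)/sqrt(sum(w_i^2))
    cauchy:      0.5 - arctan(T)/pi, T = sum(w_i tan((0.5 - p_i) pi))/sum(w_i)

    All methods return exactly p for a single input. Zeros must be floored
    by the caller first (see :class:`PoolingSpec`).
    """
    method = spec.method if isinstance(spec, PoolingSpec) else spec
    ps_arr = np.asarray(ps, dtype=float)
    if ps_arr.size == 0:
        raise DomainError("cannot pool an empty p-value sequence")
    if np.any(ps_arr <= 0) or np.any(ps_arr > 1):
        raise DomainError("p-values must lie in (0, 1]; floor zeros first")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != ps_arr.shape:
            raise DomainError("weights must match p-values in length")
        if np.any(w <= 0):
            raise DomainError("weights must be positive")
    else:
        w = np.ones_like(ps_arr)

    k = ps_arr.size
    if method == "fisher":
        stat = -2.0 * np.sum(np.log(ps_arr))
        p = float(chi2.sf(stat, df=2 * k))
    elif method == "stouffer":
        z = norm.isf(ps_arr)
        p = float(norm.sf(np.sum(z) / math.sqrt(k)))
    elif method == "weighted_z":
        z = norm.isf(ps_arr)
        p = float(norm.sf(np.sum(w * z) / math.sqrt(np.sum(w * w))))
    elif method == "cauchy":
        t = float(np.sum(w * np.tan((0.5 - ps_arr) * np.pi)) / np.sum(w))
        p = 0.5 - math.atan(t) / math.pi
    else:
        raise DomainError(f"unknown pooling method {method!r}")
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def cap_pvalue(p: float, floor: float) -> float:
    """Bound a p-value below by the display floor: max(p, floor)."""
    if not 0 < floor < 1:
        raise DomainError(f"floor must lie in (0, 1), got {floor}")
    return max(p, floor)


@dataclass(frozen=True)
class ClusterSummaryRow:
    """Pooled result for one (cluster, condition, regulation) cell."""

    cluster_id: int
    condition: str
    regulation: str
    pooled_p: float
    n_terms_total: int  # unique terms anywhere in the cluster
    n_terms_here: int   # terms contributing in this cell
    n_genes: int        # unique overlap genes in this cell
    genes: frozenset[str]
    terms: tuple[str, ...] = ()
    annotation: str | None = None

    def __post_init__(self):
        if self.n_terms_here > self.n_terms_total:
            raise ConsistencyError("n_terms_here cannot exceed n_terms_total")


def summarize_clusters(
    hits: Sequence[EnrichmentHit],
    assignment: ClusterAssignment,
    spec: PoolingSpec = PoolingSpec(),
    use_raw: bool = False,
) -> list[ClusterSummaryRow]:
    """Pool p-values per (cluster, condition, regulation) cell.

    Contributing hits are the cluster's terms observed in that condition and
    regulation. A term retained from several databases in one cell is
    collapsed to a single entry (minimum adjusted p, union of overlap genes)
    before pooling. Pooling uses adjusted p-values (raw with ``use_raw``),
    floored at ``spec.floor``; the pooled value is capped at the floor too.
    """
    for h in hits:
        if h.term not in assignment.labels:
            raise ConsistencyError(f"term {h.term!r} missing from cluster assignment")
    cluster_terms: dict[int, set[str]] = {}
    for h in hits:
        cluster_terms.setdefault(assignment.labels[h.term], set()).add(h.term)

    cells: dict[tuple[int, str, str], dict[str, tuple[float, set[str]]]] = {}
    for h in hits:
        cid = assignment.labels[h.term]
        key = (cid, h.condition, h.regulation)
        p = h.p_raw if use_raw else h.p_adj
        per_term = cells.setdefault(key, {})
        if h.term in per_term:
            old_p, old_genes = per_term[h.term]
            per_term[h.term] = (min(old_p, p), old_genes | set(h.overlap_genes))
        else:
            per_term[h.term] = (p, set(h.overlap_genes))

    rows: list[ClusterSummaryRow] = []
    for (cid, condition, regulation) in sorted(cells):
        per_term = cells[(cid, condition, regulation)]
        terms = sorted(per_term)
        ps = [cap_pvalue(per_term[t][0], spec.floor) for t in terms]
        if spec.weights == "overlap_size":
            weights = [float(len(per_term[t][1])) for t in terms]
        else:
            weights = [1.0] * len(terms)
        if spec.method in ("weighted_z", "cauchy"):
            pooled = pool_pvalues(ps, spec, weights=weights)
        else:
            pooled = pool_pvalues(ps, spec)
        genes = frozenset().union(*(per_term[t][1] for t in terms))
        rows.append(
            ClusterSummaryRow(
                cluster_id=cid,
                condition=condition,
                regulation=regulation,
                pooled_p=cap_pvalue(pooled, spec.floor),
                n_terms_total=len(cluster_terms[cid]),
                n_terms_here=len(terms),
                n_genes=len(genes),
                genes=genes,
                terms=tuple(terms),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Annotation: prompt generation, reply parsing, mapping application
# ---------------------------------------------------------------------------

PROMPT_HEADER = (
    "You are annotating clusters of enriched gene-set terms from a "
    "transcriptomics analysis. For every cluster below, reply with one short "
    "biological label (a few words) capturing the shared biology of its "
    "member terms. Respond ONLY with one line per cluster in the exact form:\n"
    "cluster_id<TAB>label\n"
)

MAX_TERMS_PER_CHUNK = 200


def build_annotation_prompt(
    assignment: ClusterAssignment,
    hits: Sequence[EnrichmentHit],
    style: Literal["terse", "detailed"] = "terse",
) -> str:
    """Deterministic LLM prompt listing each cluster's member terms.

    In "detailed" style each term carries its source database. Prompts
    covering more than 200 terms are split into numbered chunks of at most
    200 terms each (large term lists can otherwise truncate LLM replies),
    every chunk repeating the reply-format instruction.
    """
    if not assignment.labels:
        raise DomainError("assignment is empty")
    term_dbs: dict[str, set[str]] = {}
    for h in hits:
        term_dbs.setdefault(h.term, set()).add(h.database)
    blocks: list[tuple[int, list[str]]] = []
    for cid, terms in sorted(assignment.clusters().items()):
        lines = []
        for term in sorted(terms):
            if style == "detailed" and term in term_dbs:
                dbs = ",".join(sorted(term_dbs[term]))
                lines.append(f"  - {term} [{dbs}]")
            else:
                lines.append(f"  - {term}")
        blocks.append((cid, lines))

    # greedy chunking on cluster boundaries; oversize clusters are split
    chunks: list[list[str]] = []
    current: list[str] = []
    current_terms = 0
    for cid, lines in blocks:
        pos = 0
        first = True
        while first or pos < len(lines):
            first = False
            room = MAX_TERMS_PER_CHUNK - current_terms
            if room == 0:
                chunks.append(current)
                current, current_terms = [], 0
                room = MAX_TERMS_PER_CHUNK
            take = lines[pos : pos + room]
            header = f"Cluster {cid}:" if pos == 0 else f"Cluster {cid} (continued):"
            current.append("\n".join([header] + take))
            current_terms += len(take)
            pos += len(take)
    if current:
        chunks.append(current)

    if len(chunks) == 1:
        return PROMPT_HEADER + "\n" + "\n\n".join(chunks[0]) + "\n"
    parts = []
    for i, chunk in enumerate(chunks, start=1):
        parts.append(
            f"=== Part {i} of {len(chunks)} ===\n"
            + PROMPT_HEADER
            + "\n"
            + "\n\n".join(chunk)
        )
    return "\n\n".join(parts) + "\n"


@dataclass(frozen=True)
class AnnotationMap:
    """cluster_id -> summary label, plus any ids not matching a cluster."""

    labels: Mapping[int, str]
    unknown_ids: tuple[int, ...] = ()

    def __getitem__(self, cid: int) -> str:
        return self.labels[cid]

    def __contains__(self, cid: int) -> bool:
        return cid in self.labels

    def get(self, cid: int, default=None):
        return self.labels.get(cid, default)


def parse_annotation_reply(
    text: str, known_ids: Sequence[int] | None = None
) -> AnnotationMap:
    """Parse "id<TAB>label" lines from an LLM reply.

    Blank lines and non-conforming lines are ignored; parsed ids absent from
    ``known_ids`` (when given) are reported in ``unknown_ids`` but kept in
    the mapping so the caller can inspect them.
    """
    labels: dict[int, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or "\t" not in line:
            continue
        left, _, right = line.partition("\t")
        try:
            cid = int(left.strip())
        except ValueError:
            continue
        label = right.strip()
        if label:
            labels[cid] = label
    if not labels:
        raise FormatError("reply contains no parseable 'id<TAB>label' lines")
    unknown: tuple[int, ...] = ()
    if known_ids is not None:
        known = set(int(i) for i in known_ids)
        unknown = tuple(sorted(cid for cid in labels if cid not in known))
    return AnnotationMap(labels=labels, unknown_ids=unknown)


def apply_annotations(
    rows: Sequence[ClusterSummaryRow],
    annotation_map: AnnotationMap | Mapping[int, str],
) -> list[ClusterSummaryRow]:
    """Fill each row's annotation, defaulting to a "Cluster <id>" placeholder.

    Re-application with a new map overwrites previous labels.
    """
    mapping = (
        annotation_map.labels
        if isinstance(annotation_map, AnnotationMap)
        else annotation_map
    )
    return [
        replace(
            row,
            annotation=mapping.get(row.cluster_id, f"Cluster {row.cluster_id}"),
        )
        for row in rows
    ]


# ---------------------------------------------------------------------------
# Cluster coherence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoherenceReport:
    """Per-term Jaccard against the rest of its cluster.

    ``per_term`` rows: term, cluster_id, jaccard_vs_rest (NaN for
    singletons). ``mean_jaccard`` averages over terms in clusters of size
    >= 2 and is None when every cluster is a singleton.
    """

    per_term: pd.DataFrame
    mean_jaccard: float | None


def term_coherence(
    term_gene_map: TermGeneMap, assignment: ClusterAssignment
) -> CoherenceReport:
    """Score how well each term's genes match the rest of its cluster."""
    missing = set(term_gene_map) - set(assignment.labels)
    if missing:
        raise ConsistencyError(f"terms missing from assignment: {sorted(missing)[:5]}")
    clusters = assignment.clusters()
    records = []
    values = []
    for term in sorted(term_gene_map):
        cid = assignment.labels[term]
        others = clusters[cid] - {term}
        others = others & set(term_gene_map)
        if others:
            rest = frozenset().union(*(term_gene_map[o] for o in others))
            j = jaccard_similarity(term_gene_map[term], rest)
            values.append(j)
        else:
            j = float("nan")
        records.append({"term": term, "cluster_id": cid, "jaccard_vs_rest": j})
    mean = float(np.mean(values)) if values else None
    return CoherenceReport(per_term=pd.DataFrame(records), mean_jaccard=mean)
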