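"""Reading and writing of gene lists, GMT libraries and result tables.

Gene symbols are whitespace-trimmed and upper-cased on input so that query
lists match library sets regardless of capitalisation conventions (Enrichr
libraries carry upper-case human symbols). Input tables are CSV or TSV with a
header line; the delimiter is auto-detected from the header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, FormatError, InputError

logger = logging.getLogger(__name__)

RESULTS_COLUMNS = [
    "cluster_id",
    "annotation",
    "term",
    "database",
    "condition",
    "regulation",
    "overlap_genes",
    "p_raw",
    "p_adj",
    "pooled_p",
]


def normalize_gene(symbol: str) -> str:
    """Trim whitespace and upper-case a gene symbol."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class ConditionGeneList:
    """One experimental condition's input genes.

    Parameters
    ----------
    condition:
        Label of the condition (cell type, treatment, ...).
    genes:
        Deduplicated, case-normalised gene symbols.
    log2fc_map:
        Optional mapping gene -> log2 fold-change; keys are a subset of
        ``genes``. Empty when the input table had no fold-change column.
    """

    condition: str
    genes: frozenset[str]
    log2fc_map: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.condition:
            raise InputError("condition label must be non-empty")
        if not self.genes:
            raise InputError(f"condition {self.condition!r} has no genes")
        extra = set(self.log2fc_map) - set(self.genes)
        if extra:
            raise InputError(
                f"log2fc_map keys not in gene set: {sorted(extra)[:5]}"
            )


@dataclass
class GeneSetLibrary:
    """A named collection of term -> gene-set mappings.

    ``background`` defaults to the union of all member sets and is used as
    the sampling universe for the hypergeometric test. It may be overridden
    with a user-supplied universe, which must contain every term's genes.
    """

    name: str
    sets: dict[str, frozenset[str]]
    background: frozenset[str] = None  # type: ignore[assignment]

    def __post_init__(self):
        for term, genes in self.sets.items():
            if not genes:
                raise FormatError(f"term {term!r} maps to an empty gene set")
        union = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        if self.background is None:
            self.background = union
        else:
            self.background = frozenset(self.background)
            missing = union - self.background
            if missing:
                raise InputError(
                    f"background is missing {len(missing)} genes present in "
                    f"the library's sets (e.g. {sorted(missing)[:5]})"
                )

    def __len__(self) -> int:
        return len(self.sets)


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_condition_table(
    path: str | Path,
    gene_col: str = "gene",
    condition_col: str = "condition",
    logfc_col: str | None = None,
) -> list[ConditionGeneList]:
    """Read a delimited gene/condition table into per-condition gene lists.

    One :class:`ConditionGeneList` is returned per distinct condition label,
    in order of first appearance. Duplicate genes within a condition are
    collapsed; the first log2FC value wins and a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input table not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise InputError(f"input table is empty: {path}")
    sep = _detect_delimiter(header)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise InputError(f"input table has no data rows: {path}")
    for col in [gene_col, condition_col] + ([logfc_col] if logfc_col else []):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path} (columns: {list(df.columns)})"
            )

    out: list[ConditionGeneList] = []
    for condition, sub in df.groupby(condition_col, sort=False):
        condition = str(condition).strip()
        genes: dict[str, float | None] = {}
        n_dup = 0
        for idx, row in sub.iterrows():
            gene = normalize_gene(row[gene_col])
            if not gene or gene == "NAN":
                raise InputError(f"empty gene symbol at row {idx + 2} of {path}")
            lfc = None
            if logfc_col:
                raw = row[logfc_col]
                try:
                    lfc = float(raw)
                except (TypeError, ValueError):
                    raise InputError(
                        f"non-numeric log2FC value {raw!r} at row {idx + 2} of {path}"
                    ) from None
            if gene in genes:
                n_dup += 1
                continue  # keep first log2FC
            genes[gene] = lfc
        if n_dup:
            logger.warning(
                "condition %r: %d duplicate gene rows collapsed (first log2FC kept)",
                condition,
                n_dup,
            )
        log2fc_map = (
            {g: v for g, v in genes.items() if v is not None} if logfc_col else {}
        )
        out.append(
            ConditionGeneList(
                condition=condition,
                genes=frozenset(genes),
                log2fc_map=log2fc_map,
            )
        )
    return out


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT gene-set library.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; the
    description field is ignored. Gene symbols are case-normalised.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            term = fields[0].strip()
            genes = frozenset(
                normalize_gene(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term name {term!r}")
            sets[term] = genes
    if not sets:
        raise InputError(f"GMT file contains no gene sets: {path}")
    return GeneSetLibrary(name=name or path.stem, sets=sets)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library back to GMT (terms sorted, genes sorted)."""
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(library.sets):
            genes = "\t".join(sorted(library.sets[term]))
            fh.write(f"{term}\t{library.name}\t{genes}\n")


def write_results_table(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write per-term result rows to a delimited text file.

    Columns: cluster_id, annotation, term, database, condition, regulation,
    overlap_genes (semicolon-joined, sorted), p_raw, p_adj, pooled_p. The
    file round-trips through :func:`read_results_table`.
    """
    if not rows:
        raise InputError("no result rows to write")
    records = []
    for row in rows:
        rec = dict(row)
        genes = rec.get("overlap_genes", ())
        if not isinstance(genes, str):
            rec["overlap_genes"] = ";".join(sorted(genes))
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"result rows lack required fields: {missing}")
    df = df[RESULTS_COLUMNS]
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    except OSError as exc:
        raise InputError(f"cannot write results table to {path}: {exc}") from exc


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_results_table`.

    ``overlap_genes`` is split back into a sorted tuple of symbols.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"annotation": str}, float_precision="round_trip"
    )
    df["overlap_genes"] = df["overlap_genes"].map(
        lambda s: tuple(s.split(";")) if isinstance(s, str) and s else ()
    )
    df["annotation"] = df["annotation"].fillna("")
    return df


# ---------------------------------------------------------------------------
# Optional Enrichr REST adapter (network-dependent; excluded from CI).
# ---------------------------------------------------------------------------

ENRICHR_BASE = "https://maayanlab.cloud/Enrichr"


def fetch_enrichr_library(library_name: str) -> GeneSetLibrary:  # pragma: no cover
    """Download an Enrichr library over HTTP and wrap it as a GeneSetLibrary.

    This adapter requires network access and is not exercised by the test
    suite; the offline GMT path is the supported contract.
    """
    import json
    from urllib.request import urlopen

    url = f"{ENRICHR_BASE}/geneSetLibrary?mode=json&libraryName={library_name}"
    with urlopen(url, timeout=60) as resp:
        payload = json.load(resp)
    terms = payload.get(library_name, {}).get("terms", {})
    sets = {
        term: frozenset(normalize_gene(g) for g in genes)
        for term, genes in terms.items()
    }
    if not sets:
        raise InputError(f"Enrichr returned no terms for {library_name!r}")
    return GeneSetLibrary(name=library_name, sets=sets)


def condition_lists_from_frame(
    df: pd.DataFrame,
    gene_col: str = "gene",
    condition_col: str = "condition",
    logfc_col: str | None = None,
) -> list[ConditionGeneList]:
    """Build condition gene lists directly from an in-memory DataFrame.

    Convenience mirror of :func:`read_condition_table` for programmatic use
    (e.g. the fixture generator); applies the same normalisation and
    first-wins duplicate rule.
    """
    lists: list[ConditionGeneList] = []
    for condition, sub in df.groupby(condition_col, sort=False):
        genes: dict[str, float | None] = {}
        for _, row in sub.iterrows():
            g = normalize_gene(row[gene_col])
            if g in genes:
                continue
            genes[g] = float(row[logfc_col]) if logfc_col else None
        lists.append(
            ConditionGeneList(
                condition=str(condition),
                genes=frozenset(genes),
                log2fc_map={g: v for g, v in genes.items() if v is not None}
                if logfc_col
                else {},
            )
        )
    return lists
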