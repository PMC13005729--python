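"""Synthetic gene-set benchmark with planted cluster structure.

The generator emulates the situation the pipeline is built for: a gene-set
library whose terms form blocks of high mutual gene overlap (redundant
terms describing one biological theme), and per-condition gene lists that
activate particular blocks. Block membership is the ground truth against
which clustering recovery (ARI) and coherence are scored.

Overlap parameters are target pairwise Jaccard similarities: two terms in
the same block share genes so that J ≈ within_block_overlap, while terms
from different blocks share a small global pool giving J ≈
between_block_overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import GeneSetLibrary

# log2FC magnitudes: block genes are clearly regulated, noise genes are not
BLOCK_LFC_LOW, BLOCK_LFC_HIGH = 1.0, 3.0
NOISE_LFC_SCALE = 0.3


@dataclass(frozen=True)
class FixtureTruth:
    """Planted structure of a generated fixture."""

    blocks: dict[int, frozenset[str]]            # block id -> member terms
    condition_blocks: dict[str, frozenset[int]]  # condition -> enriched blocks
    params: dict = field(default_factory=dict)

    def term_labels(self) -> dict[str, int]:
        """Term -> planted block id (the reference partition)."""
        return {t: b for b, terms in self.blocks.items() for t in terms}


def _pair_intersection(genes_per_term: int, jaccard: float) -> int:
    """Intersection size giving pairwise Jaccard ``jaccard`` between two
    equal-size sets of ``genes_per_term`` genes: |A∩B| = 2gJ/(1+J)."""
    return int(round(2.0 * genes_per_term * jaccard / (1.0 + jaccard)))


def generate_fixture(
    n_blocks: int = 3,
    terms_per_block: int = 4,
    genes_per_term: int = 30,
    within_block_overlap: float = 0.8,
    between_block_overlap: float = 0.05,
    n_conditions: int = 4,
    noise_genes: int = 5,
    seed: int = 0,
) -> tuple[GeneSetLibrary, pd.DataFrame, FixtureTruth]:
    """Generate a planted-block library plus per-condition gene tables.

    Each block has a core shared by all its terms; a small global pool
    shared by every term sets the between-block overlap. Blocks are
    assigned to conditions round-robin so every block is enriched in at
    least one condition (when n_conditions >= n_blocks every condition gets
    exactly one block). Condition gene lists are the union of the assigned
    blocks' genes plus ``noise_genes`` decoys outside the library, with
    log2 fold-changes that mark block genes as regulated (sign alternating
    by block) and decoys as flat. Identical seeds give identical output.
    """
    if not (0 <= between_block_overlap <= 1 and 0 <= within_block_overlap <= 1):
        raise ConfigurationError("overlap fractions must lie in [0, 1]")
    if within_block_overlap <= between_block_overlap:
        raise ConfigurationError(
            "within_block_overlap must exceed between_block_overlap"
        )
    rng = np.random.default_rng(seed)

    m_global = _pair_intersection(genes_per_term, between_block_overlap)
    i_within = _pair_intersection(genes_per_term, within_block_overlap)
    core_size = max(1, i_within - m_global)
    peri_size = genes_per_term - core_size - m_global
    if peri_size < 0:
        raise ConfigurationError(
            "genes_per_term too small for the requested overlaps"
        )

    global_pool = frozenset(f"SHARED{i:03d}" for i in range(m_global))
    sets: dict[str, frozenset[str]] = {}
    blocks: dict[int, set[str]] = {}
    for b in range(1, n_blocks + 1):
        core = frozenset(f"B{b:02d}CORE{i:03d}" for i in range(core_size))
        blocks[b] = set()
        for t in range(1, terms_per_block + 1):
            term = f"Block{b:02d}_Term{t:02d}"
            peri = frozenset(
                f"B{b:02d}T{t:02d}PERI{i:03d}" for i in range(peri_size)
            )
            sets[term] = core | global_pool | peri
            blocks[b].add(term)

    library = GeneSetLibrary(name="planted_blocks", sets=sets)

    condition_blocks: dict[str, frozenset[int]] = {}
    rows = []
    for c in range(n_conditions):
        condition = f"cond{c + 1:02d}"
        if n_conditions < n_blocks:
            assigned = frozenset(
                b + 1 for b in range(n_blocks) if b % n_conditions == c
            )
        else:
            assigned = frozenset({c % n_blocks + 1})
        condition_blocks[condition] = assigned
        genes: set[str] = set()
        gene_block: dict[str, int] = {}
        for b in sorted(assigned):
            for term in sorted(blocks[b]):
                for g in sets[term]:
                    gene_block[g] = b
                genes |= sets[term]
        for g in sorted(genes):
            sign = 1.0 if gene_block[g] % 2 == 1 else -1.0
            lfc = sign * rng.uniform(BLOCK_LFC_LOW, BLOCK_LFC_HIGH)
            rows.append({"gene": g, "condition": condition, "log2fc": lfc})
        for i in range(noise_genes):
            rows.append(
                {
                    "gene": f"NOISE{c:02d}X{i:03d}",
                    "condition": condition,
                    "log2fc": float(rng.normal(0.0, NOISE_LFC_SCALE)),
                }
            )
    table = pd.DataFrame(rows, columns=["gene", "condition", "log2fc"])

    truth = FixtureTruth(
        blocks={b: frozenset(t) for b, t in blocks.items()},
        condition_blocks=condition_blocks,
        params={
            "n_blocks": n_blocks,
            "terms_per_block": terms_per_block,
            "genes_per_term": genes_per_term,
            "within_block_overlap": within_block_overlap,
            "between_block_overlap": between_block_overlap,
            "n_conditions": n_conditions,
            "noise_genes": noise_genes,
            "seed": seed,
        },
    )
    return library, table, truth
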