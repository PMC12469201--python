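"""Simple baseline cytokine-activity scorers used in the benchmark.

All comparators return a ``(scores, skipped)`` pair: a cells x cytokines
DataFrame and a dict naming any cytokine that could not be scored and why.
Nothing is ever silently zero-filled.  Unlike the signed VAM scores these
are raw expression summaries — they are comparable only within a column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix

__all__ = [
    "LigandReceptorMap",
    "match_cytokine_genes",
    "naive_ligand_score",
    "receptor_score",
    "product_score",
    "mean_set_score",
    "truncate_ranked_set",
]


@dataclass
class LigandReceptorMap:
    """Ligand gene -> receptor gene list (user-supplied database)."""

    entries: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lig, recs in self.entries.items():
            if not lig:
                raise ValueError("ligand gene ids must be non-empty")
            if not recs or any(not r for r in recs):
                raise ValueError(f"receptor list for {lig!r} must be non-empty strings")

    def receptors_for(self, ligand: str) -> list[str]:
        return self.entries.get(ligand, [])


def match_cytokine_genes(
    cytokines: list[str], gene_ids: list[str], alias: dict[str, str] | None = None
) -> dict[str, str]:
    """Case-insensitive exact match of cytokine names to ligand gene ids.

    An optional alias table (cytokine name -> gene id) is consulted first;
    no fuzzy matching is attempted.
    """
    lower = {g.lower(): g for g in gene_ids}
    alias = {k.lower(): v for k, v in (alias or {}).items()}
    out = {}
    for c in cytokines:
        target = alias.get(c.lower(), c)
        hit = lower.get(target.lower())
        if hit is not None:
            out[c] = hit
    return out


def _frame(cols: dict[str, np.ndarray], expr: ExpressionMatrix) -> pd.DataFrame:
    return pd.DataFrame(cols, index=expr.cell_ids)


def naive_ligand_score(
    expr: ExpressionMatrix, cytokine_to_gene: dict[str, str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Normalized expression of the ligand gene itself as the activity proxy."""
    if not cytokine_to_gene:
        raise ValueError("cytokine_to_gene map is empty")
    gi = expr.gene_index()
    cols: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    for cyt, gene in cytokine_to_gene.items():
        if gene in gi:
            cols[cyt] = expr.values[:, gi[gene]]
        else:
            skipped[cyt] = f"ligand gene {gene!r} absent from the data"
    return _frame(cols, expr), skipped


def receptor_score(
    expr: ExpressionMatrix,
    lr_map: LigandReceptorMap,
    cytokine_to_gene: dict[str, str],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Mean normalized expression of the cytokine's receptor transcripts."""
    gi = expr.gene_index()
    cols: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    for cyt, ligand in cytokine_to_gene.items():
        receptors = [r for r in lr_map.receptors_for(ligand) if r in gi]
        if not receptors:
            skipped[cyt] = f"no receptor of ligand {ligand!r} present in the data"
            continue
        cols[cyt] = expr.values[:, [gi[r] for r in receptors]].mean(axis=1)
    return _frame(cols, expr), skipped


def product_score(
    expr: ExpressionMatrix,
    lr_map: LigandReceptorMap,
    cytokine_to_gene: dict[str, str],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Ligand expression times mean receptor expression, per cell."""
    gi = expr.gene_index()
    cols: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    for cyt, ligand in cytokine_to_gene.items():
        if ligand not in gi:
            skipped[cyt] = f"ligand gene {ligand!r} absent from the data"
            continue
        receptors = [r for r in lr_map.receptors_for(ligand) if r in gi]
        if not receptors:
            skipped[cyt] = f"no receptor of ligand {ligand!r} present in the data"
            continue
        lig = expr.values[:, gi[ligand]]
        rec = expr.values[:, [gi[r] for r in receptors]].mean(axis=1)
        cols[cyt] = lig * rec
    return _frame(cols, expr), skipped


def truncate_ranked_set(genes: list[str], k: int) -> list[str]:
    """Keep the first k genes of an already-ranked list (rank order kept)."""
    if k < 1:
        raise ValueError("k must be positive")
    return list(genes[:k])


def mean_set_score(
    expr: ExpressionMatrix,
    sets: dict[str, list[str]],
    top_k: int | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Unweighted mean expression over each (optionally truncated) gene set.

    ``sets`` maps a cytokine/pathway name to a gene list; when the list is
    ranked and ``top_k`` is given, only the top k genes are used (k = 30
    reproduces the positive-top-30 construction of perturbation-set
    baselines).
    """
    gi = expr.gene_index()
    cols: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    for name, genes in sets.items():
        use = truncate_ranked_set(genes, top_k) if top_k is not None else list(genes)
        matched = [g for g in use if g in gi]
        if not matched:
            skipped[name] = "no set gene present in the data"
            continue
        cols[name] = expr.values[:, [gi[g] for g in matched]].mean(axis=1)
    return _frame(cols, expr), skipped
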