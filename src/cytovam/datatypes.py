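"""Core in-memory containers shared by every stage of the pipeline.

The internal matrix convention is cells x genes throughout (rows are cells
or spatial spots, columns are genes), matching the dominant Python
single-cell ecosystem.  Values are held densely as float64; on-disk sparse
input is densified on read, which is appropriate at the scales this package
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Sign",
    "ExpressionMatrix",
    "WeightedGeneSet",
    "SignatureCollection",
    "SignedSignature",
    "ScoreMatrix",
    "LabeledDataset",
]


def _check_unique(ids, what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = seen.get(x, 0) + 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


class Sign(str, Enum):
    """Direction of regulation for a weighted gene set."""

    positive = "positive"
    negative = "negative"


@dataclass
class ExpressionMatrix:
    """A cells x genes matrix of normalized (log-scale) expression.

    Parameters
    ----------
    values : ndarray, shape (n_cells, n_genes)
        Finite, non-negative log-normalized expression.
    gene_ids, cell_ids : sequences of unique strings
        Column and row identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if hasattr(self.values, "toarray"):  # pragma: no cover - safety net
            self.values = self.values.toarray()
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} gene columns but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} cell rows but {len(self.cell_ids)} cell ids"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=np.float64), list(df.columns), list(df.index))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class WeightedGeneSet:
    """One signed gene set for one cytokine: genes with positive weights.

    Weights are the absolute log2 fold-changes from the differential
    expression analysis that produced the set; ``sign`` records whether the
    genes were up- (positive) or down-regulated (negative) under
    stimulation.
    """

    name: str
    sign: Sign
    genes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.sign = Sign(self.sign)
        self.genes = [str(g) for g in self.genes]
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 1 or len(self.genes) != self.weights.size:
            raise ValueError("genes and weights must have matching length")
        _check_unique(self.genes, f"genes in set {self.name}/{self.sign.value}")
        if self.weights.size and (
            not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0)
        ):
            raise ValueError(f"weights in set {self.name}/{self.sign.value} must be finite and > 0")

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedGeneSet):
            return NotImplemented
        return (
            self.name == other.name
            and self.sign == other.sign
            and self.genes == other.genes
            and np.array_equal(self.weights, other.weights)
        )


@dataclass
class SignedSignature:
    """The positive/negative weighted gene-set pair for one cytokine."""

    positive: WeightedGeneSet
    negative: WeightedGeneSet

    def __post_init__(self) -> None:
        if self.positive.sign is not Sign.positive or self.negative.sign is not Sign.negative:
            raise ValueError("signature pair must hold a positive and a negative set")
        if self.positive.name != self.negative.name:
            raise ValueError("both sets of a signature must share the cytokine name")
        shared = set(self.positive.genes) & set(self.negative.genes)
        if shared:
            raise ValueError(
                f"genes present in both signs of {self.positive.name}: {sorted(shared)}"
            )

    @property
    def name(self) -> str:
        return self.positive.name


@dataclass
class SignatureCollection:
    """All per-cytokine signed signatures plus per-gene provenance.

    ``provenance`` is a DataFrame with columns (cytokine, gene, log2fc,
    p_value, p_adjusted); p-values may be NaN when the collection was read
    from disk rather than built from data.  The invariant |log2fc| == weight
    holds for every retained gene.
    """

    cytokines: dict[str, SignedSignature]
    provenance: pd.DataFrame = field(default_factory=lambda: _empty_provenance())
    num_genes_requested: int = 60

    def __post_init__(self) -> None:
        if self.num_genes_requested < 1:
            raise ValueError("num_genes_requested must be positive")
        for name, sig in self.cytokines.items():
            if name != sig.name:
                raise ValueError(f"signature keyed {name!r} is named {sig.name!r}")
            if len(sig.positive) + len(sig.negative) > self.num_genes_requested:
                raise ValueError(
                    f"{name}: n_pos + n_neg exceeds num_genes_requested "
                    f"({len(sig.positive)} + {len(sig.negative)} > {self.num_genes_requested})"
                )

    @property
    def names(self) -> list[str]:
        return list(self.cytokines)

    @property
    def n_sets(self) -> int:
        """Number of non-empty signed sets across all cytokines."""
        return sum(
            (len(s.positive) > 0) + (len(s.negative) > 0) for s in self.cytokines.values()
        )

    def __len__(self) -> int:
        return len(self.cytokines)

    def __getitem__(self, name: str) -> SignedSignature:
        return self.cytokines[name]


def _empty_provenance() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["cytokine", "gene", "log2fc", "p_value", "p_adjusted"]
    ).astype({"log2fc": float, "p_value": float, "p_adjusted": float})


class ScoreComponent(str, Enum):
    combined = "combined"
    positive_only = "positive_only"
    negative_only = "negative_only"


@dataclass
class ScoreMatrix:
    """Cells x cytokines activity scores, each in [0, 1].

    Cytokines whose signatures matched no gene in the target data are
    absent from the matrix entirely (they are reported by the scorer, never
    silently zero-filled).
    """

    values: np.ndarray
    cell_ids: list[str]
    cytokine_ids: list[str]
    component: ScoreComponent = ScoreComponent.combined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.component = ScoreComponent(self.component)
        if self.values.shape != (len(self.cell_ids), len(self.cytokine_ids)):
            raise ValueError("score matrix shape does not match id lists")
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.cytokine_ids, "cytokine ids")
        if self.values.size and (
            np.any(~np.isfinite(self.values))
            or np.any(self.values < -1e-12)
            or np.any(self.values > 1 + 1e-12)
        ):
            raise ValueError("scores must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.cytokine_ids)


@dataclass
class LabeledDataset:
    """Expression plus a per-cell stimulation-condition label.

    Labels are cytokine names, or a control label (e.g. ``"PBS"``) for
    vehicle-injected animals.
    """

    expr: ExpressionMatrix
    labels: list[str]

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.expr.n_cells:
            raise ValueError(
                f"{len(self.labels)} labels for {self.expr.n_cells} cells"
            )
        if any(l == "" for l in self.labels):
            raise ValueError("labels must be non-empty strings")

    def label_counts(self) -> Mapping[str, int]:
        return pd.Series(self.labels).value_counts().to_dict()
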