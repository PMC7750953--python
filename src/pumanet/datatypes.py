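"""Core in-memory containers for bipartite regulatory network inference.

All containers are thin wrappers around numpy arrays with ordered ID labels,
in the style of the field's network toolkits: the heavy lifting is done by
module-level functions, the containers guarantee shape/label consistency.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RegulatoryNetwork",
    "ExpressionMatrix",
    "CoexpressionNetwork",
    "CooperativityNetwork",
    "PumaParams",
    "NetworkCollection",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate {what} IDs: {dupes[:5]}")
    return ids


@dataclass
class RegulatoryNetwork:
    """Bipartite regulator x gene network with real-valued edge weights.

    ``weights[i, j]`` is the (z-score-like) weight of the edge from
    regulator ``regulators[i]`` to gene ``genes[j]``.  ``mirna_mask`` flags
    which regulators are miRNAs; during message passing their cooperativity
    rows/columns are pinned to the prior.
    """

    regulators: list[str]
    genes: list[str]
    weights: np.ndarray
    mirna_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.regulators = _check_unique(self.regulators, "regulator")
        self.genes = _check_unique(self.genes, "gene")
        self.weights = np.asarray(self.weights, dtype=float)
        m, n = len(self.regulators), len(self.genes)
        if self.weights.shape != (m, n):
            raise ValueError(
                f"weights shape {self.weights.shape} != ({m} regulators, {n} genes)"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("network weights must be finite")
        if self.mirna_mask is None:
            self.mirna_mask = np.zeros(m, dtype=bool)
        else:
            self.mirna_mask = np.asarray(self.mirna_mask, dtype=bool)
            if self.mirna_mask.shape != (m,):
                raise ValueError("mirna_mask length must equal number of regulators")

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def mirna_ids(self) -> list[str]:
        return [r for r, f in zip(self.regulators, self.mirna_mask) if f]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix for one tissue/condition."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    tissue_label: str = ""

    def __post_init__(self) -> None:
        self.genes = _check_unique(self.genes, "gene")
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"expression shape {self.values.shape} != "
                f"({len(self.genes)} genes, {len(self.samples)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CoexpressionNetwork:
    """Symmetric gene-gene co-expression (correlation) matrix."""

    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = _check_unique(self.genes, "gene")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("co-expression matrix must be square on the gene set")


@dataclass
class CooperativityNetwork:
    """Symmetric regulator-regulator cooperativity matrix.

    Identity by default for miRNA-only runs: sequence-based priors carry no
    cooperativity information between miRNAs, so each regulator initially
    cooperates only with itself.
    """

    regulators: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.regulators = _check_unique(self.regulators, "regulator")
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.regulators)
        if self.values.shape != (m, m):
            raise ValueError("cooperativity matrix must be square on the regulator set")

    @classmethod
    def identity(cls, regulators: Sequence[str]) -> "CooperativityNetwork":
        return cls(list(regulators), np.eye(len(regulators)))


@dataclass
class PumaParams:
    """Message-passing hyperparameters.

    alpha   learning rate of the convex update, in (0, 1]
    tol     convergence threshold on the hamming distance h (mean absolute
            difference between the network and its message-based candidate)
    max_iter upper bound on iterations; non-convergence is a warning, not an error
    seed    reserved for stochastic tie-breaking (the engine itself is
            deterministic)
    """

    alpha: float = 0.1
    tol: float = 1e-3
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 0:
            raise ValueError(f"max_iter must be >= 0, got {self.max_iter}")


@dataclass
class NetworkCollection:
    """A named set of same-shape networks, one per tissue."""

    tissues: list[str]
    networks: list[RegulatoryNetwork]

    def __post_init__(self) -> None:
        self.tissues = _check_unique(self.tissues, "tissue")
        if len(self.tissues) != len(self.networks):
            raise ValueError("one network per tissue required")
        if not self.networks:
            raise ValueError("empty collection")
        ref = self.networks[0]
        for t, net in zip(self.tissues, self.networks):
            if net.regulators != ref.regulators or net.genes != ref.genes:
                raise ValueError(
                    f"network for tissue {t!r} has mismatched regulator/gene ordering"
                )

    def __len__(self) -> int:
        return len(self.tissues)

    def weight_stack(self) -> np.ndarray:
        """Stack edge weights into a (tissues, regulators, genes) array."""
        return np.stack([net.weights for net in self.networks], axis=0)
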