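"""Tissue-specificity scoring of edges and miRNA expression across tissues.

An edge weight that stands out from its own cross-tissue distribution marks a
tissue-specific interaction.  The score is the deviation of the weight in one
tissue from the cross-tissue median, in units of the cross-tissue IQR:

    s_ij(t) = (w_ij(t) - med_t' w_ij(t')) / IQR_t' w_ij(t')

An edge with s_ij(t) > 2 is called specific to tissue t, and its multiplicity
m_ij counts the tissues it is specific to.  miRNA expression specificity is
scored analogously from per-tissue sample medians against the pooled
distribution.  Quartiles use linear interpolation between order statistics;
a zero IQR yields score 0 (an invariant weight is by definition not specific).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, NetworkCollection, RegulatoryNetwork

__all__ = [
    "SpecificityScores",
    "EdgeClassification",
    "edge_specificity",
    "multiplicity",
    "expression_specificity",
    "classify_edges",
    "compare_collections",
    "prior_overlap",
]

EDGE_CLASSES = ("canonical", "non-canonical", "different")


def _robust_scale(values: np.ndarray, center: np.ndarray, axis: int = 0) -> np.ndarray:
    """(values - center)/IQR along ``axis``; zero IQR maps to score 0."""
    q1, q3 = np.percentile(values, [25, 75], axis=axis, method="linear")
    iqr = q3 - q1
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (np.moveaxis(values, axis, 0) - center) / iqr
    s = np.where(iqr == 0, 0.0, s)
    return np.moveaxis(s, 0, axis)


@dataclass
class SpecificityScores:
    """Per-edge tissue-specificity scores over a tissue collection."""

    tissues: list[str]
    regulators: list[str]
    genes: list[str]
    scores: np.ndarray  # (tissues, regulators, genes)
    threshold: float = 2.0
    multiplicity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        T = len(self.tissues)
        if self.scores.shape != (T, len(self.regulators), len(self.genes)):
            raise ValueError("scores shape inconsistent with labels")
        self.multiplicity = (self.scores > self.threshold).sum(axis=0)

    def tissue(self, name: str) -> np.ndarray:
        return self.scores[self.tissues.index(name)]

    def targeting_profile(self, regulator: str, tissue: str) -> pd.Series:
        """Per-gene specificity scores of one regulator in one tissue,
        the ranked input of a pre-ranked enrichment run."""
        i = self.regulators.index(regulator)
        return pd.Series(self.tissue(tissue)[i], index=self.genes, name=f"{regulator}|{tissue}")

    def to_frame(self) -> pd.DataFrame:
        """Long format: regulator, gene, tissue, score."""
        T, m, n = self.scores.shape
        return pd.DataFrame(
            {
                "regulator": np.repeat(self.regulators, n * T),
                "gene": np.tile(np.repeat(self.genes, T), m),
                "tissue": np.tile(self.tissues, m * n),
                "score": self.scores.transpose(1, 2, 0).ravel(),
            }
        )


def edge_specificity(coll: NetworkCollection, threshold: float = 2.0) -> SpecificityScores:
    """Score every edge's deviation from its cross-tissue median in IQR units."""
    if len(coll) < 3:
        raise ValueError(f"need >= 3 tissues for median/IQR, got {len(coll)}")
    W = coll.weight_stack()  # (T, m, n)
    med = np.median(W, axis=0)
    s = _robust_scale(W, med, axis=0)
    ref = coll.networks[0]
    return SpecificityScores(list(coll.tissues), ref.regulators, ref.genes, s, threshold)


def multiplicity(scores: SpecificityScores, threshold: float = 2.0) -> np.ndarray:
    """Number of tissues each edge is specific to (strict s > threshold)."""
    return (scores.scores > threshold).sum(axis=0)


def expression_specificity(
    expr_by_tissue: dict[str, ExpressionMatrix] | list[ExpressionMatrix],
    mirna_ids: list[str],
) -> pd.DataFrame:
    """Tissue-specificity of miRNA expression levels.

    For miRNA p and tissue t: (median over tissue-t samples minus the median
    over ALL samples) divided by the IQR over all samples.  Returns a
    (miRNA x tissue) DataFrame of scores.
    """
    if isinstance(expr_by_tissue, list):
        expr_by_tissue = {e.tissue_label or f"tissue{i}": e for i, e in enumerate(expr_by_tissue)}
    tissues = list(expr_by_tissue)
    for name, expr in expr_by_tissue.items():
        missing = sorted(set(mirna_ids) - set(expr.genes))
        if missing:
            raise ValueError(
                f"miRNA {missing[0]!r} missing from expression matrix of tissue {name!r}"
            )
    out = np.empty((len(mirna_ids), len(tissues)))
    for i, mir in enumerate(mirna_ids):
        pooled = np.concatenate(
            [expr.values[expr.genes.index(mir)] for expr in expr_by_tissue.values()]
        )
        med_all = np.median(pooled)
        q1, q3 = np.percentile(pooled, [25, 75], method="linear")
        iqr = q3 - q1
        for j, name in enumerate(tissues):
            expr = expr_by_tissue[name]
            med_t = np.median(expr.values[expr.genes.index(mir)])
            out[i, j] = 0.0 if iqr == 0 else (med_t - med_all) / iqr
    return pd.DataFrame(out, index=mirna_ids, columns=tissues)


@dataclass
class EdgeClassification:
    """Partition of all edges by their support in two priors."""

    regulators: list[str]
    genes: list[str]
    labels: np.ndarray  # (m, n) array of strings from EDGE_CLASSES

    def counts(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in EDGE_CLASSES}

    def mask(self, cls: str) -> np.ndarray:
        if cls not in EDGE_CLASSES:
            raise ValueError(f"unknown edge class {cls!r}; expected one of {EDGE_CLASSES}")
        return self.labels == cls


def classify_edges(priorA: RegulatoryNetwork, priorB: RegulatoryNetwork) -> EdgeClassification:
    """Label edges as canonical (in both priors), non-canonical (in neither)
    or different (in exactly one)."""
    if priorA.regulators != priorB.regulators or priorA.genes != priorB.genes:
        raise ValueError("priors must share the same regulator/gene universe and order")
    a = priorA.weights != 0
    b = priorB.weights != 0
    labels = np.where(a & b, "canonical", np.where(~a & ~b, "non-canonical", "different"))
    return EdgeClassification(list(priorA.regulators), list(priorA.genes), labels)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan  # undefined on zero-variance input; reported as NaN
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_collections(
    a: SpecificityScores,
    b: SpecificityScores,
    classes: EdgeClassification | None = None,
) -> pd.DataFrame:
    """Pearson correlation of tissue-specificity scores between two collections.

    One row per tissue (and per edge class when a classification is given),
    with columns tissue, edge_class, r, p, n_edges.
    """
    if a.tissues != b.tissues:
        raise ValueError("collections cover different tissue sets")
    if a.scores.shape != b.scores.shape:
        raise ValueError("collections have different shapes")
    rows = []
    strata: list[tuple[str, np.ndarray | None]] = [("all", None)]
    if classes is not None:
        strata += [(c, classes.mask(c)) for c in EDGE_CLASSES]
    for t_idx, tissue in enumerate(a.tissues):
        sa, sb = a.scores[t_idx], b.scores[t_idx]
        for cls, mask in strata:
            xa = sa.ravel() if mask is None else sa[mask]
            xb = sb.ravel() if mask is None else sb[mask]
            r, p = _pearson(xa, xb)
            rows.append(
                {"tissue": tissue, "edge_class": cls, "r": r, "p": p, "n_edges": xa.size}
            )
    return pd.DataFrame(rows)


def prior_overlap(priorA: RegulatoryNetwork, priorB: RegulatoryNetwork) -> dict[str, float]:
    """Jaccard index over nonzero edge sets and Pearson correlation of weights."""
    if priorA.weights.shape != priorB.weights.shape:
        raise ValueError("priors have different shapes")
    a, b = priorA.weights != 0, priorB.weights != 0
    union = (a | b).sum()
    jac = float((a & b).sum() / union) if union else np.nan
    r, p = _pearson(priorA.weights.ravel(), priorB.weights.ravel())
    return {"jaccard": jac, "pearson_r": r, "pearson_p": p}
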