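"""Pre-ranked gene set enrichment on tissue-specific targeting profiles.

A miRNA's targeting profile in a tissue is the vector of tissue-specificity
scores of all genes for their edge to that miRNA.  Ranking the profile and
walking a weighted Kolmogorov-Smirnov running sum over each gene set yields
an enrichment score (ES): the maximal deviation of the walk, positive when
set members concentrate at the top of the ranking.  Significance comes from a
seeded permutation null (random gene labels), and the false discovery rate
from the standard normalized-ES pooling procedure (Benjamini-Hochberg on the
permutation p-values is available as a fallback).  Each association is
summarized by the signed score -log10(FDR) x sign(ES), with FDR floored at
1/(nperm + 1) — the resolution of the permutation test.

Conventions: running-sum weight exponent 1 (hit increments proportional to
|score|), gene sets restricted to genes present in the profile and to sizes
within [min_size, max_size], ties in the ranking broken by a seeded random
permutation.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "preranked_gsea",
    "signed_go_scores",
    "profile_similarity",
    "cross_tissue_null",
]


@dataclass
class EnrichmentResult:
    gene_set: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr: float
    signed_score: float


def rank_genes(profile: pd.Series, seed: int = 0) -> pd.Series:
    """Sort a profile in decreasing score order, breaking ties at random.

    The tie-break permutation is drawn from ``seed`` so ranked order (and
    everything downstream) is reproducible.
    """
    rng = np.random.default_rng(seed)
    scores = profile.to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("targeting profile contains non-finite scores")
    jitter = rng.permutation(len(scores))  # secondary key: random but seeded
    order = np.lexsort((jitter, -scores))
    return profile.iloc[order]


def enrichment_score(ranked_scores: np.ndarray, member_mask: np.ndarray) -> float:
    """ES of one gene set against a ranked profile (weight exponent 1).

    The running sum gains |score|/sum(|scores in set|) at each member and
    loses 1/(N - Nh) at each non-member; the ES is the extremum of the walk.
    """
    s = np.abs(np.asarray(ranked_scores, dtype=float))
    hit = np.asarray(member_mask, dtype=bool)
    n = s.size
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must be a proper nonempty subset of the profile")
    nr = s[hit].sum()
    delta = np.where(hit, 0.0 if nr == 0 else s / nr, -1.0 / (n - nh))
    if nr == 0:  # all member scores zero: hits contribute equal flat steps
        delta[hit] = 1.0 / nh
    walk = np.cumsum(delta)
    return float(walk[np.argmax(np.abs(walk))])


def _null_es(
    ranked_scores: np.ndarray, set_size: int, nperm: int, rng: np.random.Generator
) -> np.ndarray:
    """Permutation null: ES of ``nperm`` random same-size gene sets."""
    n = ranked_scores.size
    s = np.abs(ranked_scores)
    # random member positions per permutation, without replacement
    pos = np.argsort(rng.random((nperm, n)), axis=1)[:, :set_size]
    hit = np.zeros((nperm, n), dtype=bool)
    np.put_along_axis(hit, pos, True, axis=1)
    nr = np.take_along_axis(np.broadcast_to(s, (nperm, n)), pos, axis=1).sum(axis=1)
    nr = np.where(nr == 0, np.inf, nr)  # degenerate all-zero draws walk flat
    miss = -1.0 / (n - set_size)
    delta = np.where(hit, s[None, :] / nr[:, None], miss)
    walk = np.cumsum(delta, axis=1)
    idx = np.argmax(np.abs(walk), axis=1)
    return walk[np.arange(nperm), idx]


def _signed_mean(null: np.ndarray, positive: bool) -> float:
    side = null[null >= 0] if positive else null[null < 0]
    if side.size == 0:
        return np.nan
    return float(np.abs(side).mean())


def preranked_gsea(
    profile: pd.Series,
    gene_sets: dict[str, list[str]],
    nperm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
    fdr_method: str = "nes",
) -> pd.DataFrame:
    """Pre-ranked enrichment of a targeting profile over a gene-set collection.

    Parameters
    ----------
    profile : per-gene scores indexed by gene ID (a targeting profile).
    gene_sets : mapping set name -> member gene IDs; members outside the
        profile are dropped, then sets outside [min_size, max_size] excluded.
    nperm, seed : size and seed of the permutation null.
    fdr_method : "nes" for the normalized-ES pooling procedure, "bh" for
        Benjamini-Hochberg on the permutation p-values.

    Returns a DataFrame with one row per surviving gene set: gene_set, size,
    es, nes, p_perm, fdr, signed_score.
    """
    if fdr_method not in ("nes", "bh"):
        raise ValueError(f"fdr_method must be 'nes' or 'bh', got {fdr_method!r}")
    ranked = rank_genes(profile, seed=seed)
    ranked_scores = ranked.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(ranked.index)}
    n = len(ranked)

    surviving: list[tuple[str, np.ndarray]] = []
    for name, members in gene_sets.items():
        idx = sorted({gene_pos[g] for g in members if g in gene_pos})
        if min_size <= len(idx) <= max_size and len(idx) < n:
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            surviving.append((name, mask))
    if not surviving:
        warnings.warn("no gene set survived filtering", UserWarning, stacklevel=2)
        return pd.DataFrame(
            columns=["gene_set", "size", "es", "nes", "p_perm", "fdr", "signed_score"]
        )

    rng = np.random.default_rng(seed)
    floor = 1.0 / (nperm + 1)
    rows, null_nes_pool = [], []
    for name, mask in surviving:
        es = enrichment_score(ranked_scores, mask)
        null = _null_es(ranked_scores, int(mask.sum()), nperm, rng)
        if es >= 0:
            same = null[null >= 0]
            p = (np.sum(same >= es) + 1) / (same.size + 1)
        else:
            same = null[null < 0]
            p = (np.sum(same <= es) + 1) / (same.size + 1)
        mean_pos = _signed_mean(null, True)
        mean_neg = _signed_mean(null, False)
        denom = mean_pos if es >= 0 else mean_neg
        nes = np.nan if not np.isfinite(denom) or denom == 0 else es / denom
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes = np.where(null >= 0, null / mean_pos, null / mean_neg)
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
        rows.append({"gene_set": name, "size": int(mask.sum()), "es": es, "nes": nes, "p_perm": float(p)})

    df = pd.DataFrame(rows)
    if fdr_method == "bh":
        df["fdr"] = multipletests(df["p_perm"].to_numpy(), method="fdr_bh")[1]
    else:
        pool = np.concatenate(null_nes_pool)
        obs = df["nes"].to_numpy()
        fdr = np.full(len(df), np.nan)
        for i, nes in enumerate(obs):
            if not np.isfinite(nes):
                continue
            if nes >= 0:
                null_frac = np.mean(pool >= nes)
                obs_frac = np.mean(obs[np.isfinite(obs)] >= nes)
            else:
                null_frac = np.mean(pool <= nes)
                obs_frac = np.mean(obs[np.isfinite(obs)] <= nes)
            fdr[i] = 1.0 if obs_frac == 0 else min(1.0, null_frac / obs_frac)
        df["fdr"] = fdr
    df["signed_score"] = -np.log10(np.maximum(df["fdr"].to_numpy(), floor)) * np.sign(
        df["es"].to_numpy()
    )
    return df


def signed_go_scores(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble signed -log10(FDR) scores into a (profile x gene set) matrix.

    ``results`` maps a profile ID (typically "miRNA|tissue") to the DataFrame
    returned by :func:`preranked_gsea`.  Missing (profile, set) cells are NaN.
    """
    series = {
        pid: df.set_index("gene_set")["signed_score"] for pid, df in results.items()
    }
    return pd.DataFrame(series).T


def profile_similarity(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation per profile between two signed-score matrices.

    Rows are matched by profile ID and columns by gene set; rows with zero
    variance yield NaN (undefined correlation, reported as such).
    """
    common_rows = scores_a.index.intersection(scores_b.index)
    common_cols = scores_a.columns.intersection(scores_b.columns)
    if len(common_cols) < 3:
        raise ValueError("need >= 3 shared gene sets for a meaningful correlation")
    rows = []
    for pid in common_rows:
        x = scores_a.loc[pid, common_cols].to_numpy(dtype=float)
        y = scores_b.loc[pid, common_cols].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"profile": pid, "r": r, "p": p, "n_sets": int(ok.sum())})
    return pd.DataFrame(rows)


def cross_tissue_null(scores: pd.DataFrame, sep: str = "|") -> np.ndarray:
    """Null correlations between mismatched tissues of the same miRNA.

    Profile IDs are "<miRNA><sep><tissue>"; for every miRNA and every ordered
    pair of distinct tissues, the Pearson correlation of the two score rows is
    collected.  Matched-tissue similarity should exceed this distribution,
    which for unrelated tissue signals centers at zero.
    """
    parsed: dict[str, dict[str, np.ndarray]] = {}
    for pid in scores.index:
        mir, _, tissue = str(pid).rpartition(sep)
        if not mir:
            raise ValueError(f"profile ID {pid!r} lacks the '{sep}' miRNA/tissue separator")
        parsed.setdefault(mir, {})[tissue] = scores.loc[pid].to_numpy(dtype=float)
    out = []
    for mir, by_tissue in parsed.items():
        for t1, t2 in _iter_permutations(sorted(by_tissue), 2):
            x, y = by_tissue[t1], by_tissue[t2]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                out.append(stats.pearsonr(x[ok], y[ok])[0])
    return np.asarray(out)
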