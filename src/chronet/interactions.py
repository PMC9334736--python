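"""Rhythmic co-expression interactions.

For a gene pair, co-expression at one time point is the Spearman
correlation of the two genes' expression across organs at that ZT.  The
resulting per-pair correlation time series (rho_1 ... rho_T) is itself
tested for 24 h rhythmicity with the same nonparametric engine used for
single genes; pairs passing BH < alpha are *rhythmic interactions*.

Pair batches are sampled uniformly without replacement (default 10,000
pairs, 100 independent repeats) for an unbiased estimate of the rhythmic
proportion; results are stratified by how many members are global cycling
genes, and external edge lists (PPI / genetic / pathway) can be pushed
through the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ExpressionAtlas
from .genesets import EdgeList
from .jtk import adjust_bh, build_references, rhythm_test_batch

__all__ = [
    "sample_pairs",
    "rank_transform",
    "correlation_series",
    "correlation_series_batch",
    "detect_rhythmic_interactions",
    "zscore_series",
    "stratify_by_cycling",
    "edge_list_rhythmicity",
]


def sample_pairs(
    genes: list[str],
    n_pairs: int = 10_000,
    n_repeats: int = 100,
    seed: int = 0,
) -> list[list[tuple[str, str]]]:
    """Sample ``n_repeats`` independent batches of distinct unordered pairs.

    Within a batch, pairs are drawn uniformly without replacement (no
    duplicates, no self-pairs); the exhaustive case ``n_pairs == C(n, 2)``
    returns every pair exactly once.  Fully reproducible from the seed.
    """
    n = len(genes)
    total = n * (n - 1) // 2
    if n < 2:
        raise ValueError("need >= 2 genes")
    if n_pairs > total:
        raise ValueError(f"n_pairs={n_pairs} exceeds C({n},2)={total}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    batches = []
    for _ in range(n_repeats):
        codes = rng.choice(total, size=n_pairs, replace=False)
        # decode linear index -> (i, j), i < j, row-major over the triangle
        i = (n - 2 - np.floor(
            np.sqrt(-8.0 * codes + 4.0 * n * (n - 1) - 7.0) / 2.0 - 0.5
        )).astype(int)
        j = (codes + i + 1 - (i * (2 * n - i - 1)) // 2).astype(int)
        batches.append([(genes[a], genes[b]) for a, b in zip(i, j)])
    return batches


def rank_transform(atlas: ExpressionAtlas) -> np.ndarray:
    """Average ranks across organs, per gene per ZT (Spearman preprocessing).

    Returns an array shaped like ``atlas.values`` whose organ axis holds the
    rank of each organ's value among all organs at that (gene, ZT).
    """
    return stats.rankdata(atlas.values, axis=1)


@dataclass
class CorrelationSeries:
    """Per-pair vector of cross-organ Spearman coefficients, one per ZT."""

    gene_a: str
    gene_b: str
    rho: np.ndarray
    undefined: np.ndarray  # boolean per ZT: zero variance in either gene

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.undefined = np.asarray(self.undefined, dtype=bool)


def correlation_series(atlas: ExpressionAtlas, pair: tuple[str, str]) -> CorrelationSeries:
    """Spearman rho across organs at every ZT for one pair (average ranks)."""
    a, b = atlas.gene_index(pair[0]), atlas.gene_index(pair[1])
    rho = np.empty(atlas.n_times)
    undefined = np.zeros(atlas.n_times, dtype=bool)
    for t in range(atlas.n_times):
        xa, xb = atlas.values[a, :, t], atlas.values[b, :, t]
        if np.all(xa == xa[0]) or np.all(xb == xb[0]):
            rho[t] = 0.0
            undefined[t] = True
            continue
        rho[t] = stats.spearmanr(xa, xb).statistic
    return CorrelationSeries(pair[0], pair[1], rho, undefined)


def correlation_series_batch(
    atlas: ExpressionAtlas,
    pairs: list[tuple[str, str]],
    ranks: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`correlation_series` over a pair batch.

    Returns ``(rho, undefined)`` with shapes (n_pairs, n_times); rho of an
    undefined time point (zero variance in either gene) is set to 0 and
    flagged.
    """
    if ranks is None:
        ranks = rank_transform(atlas)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))  # genes x times
    idx_a = np.array([atlas.gene_index(p[0]) for p in pairs])
    idx_b = np.array([atlas.gene_index(p[1]) for p in pairs])
    num = (centered[idx_a] * centered[idx_b]).sum(axis=1)  # pairs x times
    den = norm[idx_a] * norm[idx_b]
    undefined = den == 0
    rho = np.zeros_like(num)
    np.divide(num, den, out=rho, where=~undefined)
    return rho, undefined


def detect_rhythmic_interactions(
    atlas: ExpressionAtlas,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    max_undefined_fraction: float = 0.25,
    ranks: np.ndarray | None = None,
    references=None,
) -> pd.DataFrame:
    """Rhythm-test the correlation series of each pair; BH within the batch.

    Pairs with more than ``max_undefined_fraction`` undefined time points
    are excluded (reported with ``excluded=True`` and NaN statistics).
    """
    rho, undefined = correlation_series_batch(atlas, pairs, ranks)
    excluded = undefined.mean(axis=1) > max_undefined_fraction
    refs = references or build_references(atlas.zt_times,
                                          periods=(atlas.period_hours,))
    table = rhythm_test_batch(rho, atlas.zt_times, refs,
                              period_hours=atlas.period_hours)
    table.insert(0, "gene_a", [p[0] for p in pairs])
    table.insert(1, "gene_b", [p[1] for p in pairs])
    table["excluded"] = excluded
    table["n_undefined"] = undefined.sum(axis=1)
    p_adj = np.full(len(table), np.nan)
    ok = ~excluded
    if ok.any():
        p_adj[ok] = adjust_bh(table.loc[ok, "p_raw"])
    table["p_adj"] = p_adj
    table["is_rhythmic"] = (table["p_adj"] < alpha) & ok
    return table


def zscore_series(rho) -> tuple[np.ndarray, bool]:
    """Standardize a correlation series: rho'_i = (rho_i - mean) / sd.

    The sd is the population (divide-by-n) standard deviation over the
    fixed set of time points.  A constant series yields flagged zeros.
    """
    rho = np.asarray(rho, dtype=float)
    sd = rho.std()
    if sd == 0:
        return np.zeros_like(rho), True
    return (rho - rho.mean()) / sd, False


def stratify_by_cycling(
    results: pd.DataFrame,
    cycling_calls: pd.Series | dict,
) -> pd.DataFrame:
    """Rhythmic proportion among pairs with both/one/neither member cycling.

    Includes a chi-square test of homogeneity across the three strata;
    empty strata are flagged with NaN proportions.
    """
    calls = pd.Series(cycling_calls)
    missing = ({*results["gene_a"], *results["gene_b"]}) - set(calls.index)
    if missing:
        raise ValueError(f"cycling calls missing for {len(missing)} genes")
    usable = results[~results["excluded"]]
    n_cyclers = (
        usable["gene_a"].map(calls).astype(int)
        + usable["gene_b"].map(calls).astype(int)
    )
    stratum = n_cyclers.map({2: "both", 1: "one", 0: "neither"})
    rows = []
    counts = []
    for name in ("both", "one", "neither"):
        sub = usable[stratum == name]
        n, k = len(sub), int(sub["is_rhythmic"].sum())
        rows.append({
            "stratum": name,
            "n_pairs": n,
            "n_rhythmic": k,
            "proportion": k / n if n else float("nan"),
            "empty": n == 0,
        })
        if n:
            counts.append([k, n - k])
    out = pd.DataFrame(rows)
    if len(counts) >= 2 and all(sum(c) for c in counts):
        try:
            chi2 = stats.chi2_contingency(np.array(counts))
            out.attrs["chi2_p"] = float(chi2.pvalue)
        except ValueError:
            out.attrs["chi2_p"] = float("nan")
    else:
        out.attrs["chi2_p"] = float("nan")
    return out


def edge_list_rhythmicity(
    atlas: ExpressionAtlas,
    edges: EdgeList,
    alpha: float = 0.05,
    ranks: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float, int]:
    """Apply the rhythmic-interaction pipeline to an external edge list.

    Edges are restricted to genes present in the atlas (drop count
    returned); duplicates collapse through the EdgeList contract.  Returns
    (per-edge table, rhythmic proportion, n_dropped_edges).
    """
    restricted, dropped = edges.restrict_to(atlas.gene_ids)
    if not len(restricted):
        raise ValueError("no edges overlap the atlas gene universe")
    pairs = sorted(restricted.pairs)
    table = detect_rhythmic_interactions(atlas, pairs, alpha, ranks=ranks)
    usable = table[~table["excluded"]]
    proportion = float(usable["is_rhythmic"].mean()) if len(usable) else float("nan")
    return table, proportion, dropped
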