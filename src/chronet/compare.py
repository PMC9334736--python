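"""Pairwise comparison of two co-expression networks (e.g. ZT06 vs ZT18).

Covers differential connectivity (>2-fold degree change), per-node
Euclidean distance between adjacency rows, pairwise weight differences
stratified by global-cycling status, Jaccard similarity between module
assignments with mutual-best consensus calling, and hub subnetwork
extraction by intramodular connectivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .network import ModuleAssignment, WeightedNetwork, UNASSIGNED

__all__ = [
    "align_networks",
    "differential_connectivity",
    "node_euclidean_distance",
    "pair_weight_difference",
    "module_jaccard",
    "hub_subnetwork",
]


def align_networks(
    net_a: WeightedNetwork, net_b: WeightedNetwork
) -> tuple[list[str], np.ndarray, np.ndarray, int]:
    """Common gene universe and re-indexed adjacencies; drop count returned."""
    common = sorted(set(net_a.nodes) & set(net_b.nodes))
    if not common:
        raise ValueError("networks share no genes")
    ia = [net_a.nodes.index(g) for g in common]
    ib = [net_b.nodes.index(g) for g in common]
    a = net_a.adjacency[np.ix_(ia, ia)]
    b = net_b.adjacency[np.ix_(ib, ib)]
    dropped = (len(net_a.nodes) - len(common)) + (len(net_b.nodes) - len(common))
    return common, a, b, dropped


def differential_connectivity(
    net_a: WeightedNetwork,
    net_b: WeightedNetwork,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Genes whose connectivity changes more than ``fold``-fold between nets.

    fold change = max(k_A, k_B) / min(k_A, k_B); when one side is exactly 0
    a machine-scale pseudo-count guards the ratio and the gene is flagged
    ``zero_guarded``.  Direction records which network is heavier.
    """
    common, a, b, _ = align_networks(net_a, net_b)
    k_a, k_b = a.sum(axis=1), b.sum(axis=1)
    zero = (k_a == 0) | (k_b == 0)
    eps = np.finfo(float).eps
    hi = np.maximum(k_a, k_b)
    lo = np.minimum(k_a, k_b)
    ratio = (hi + np.where(zero, eps, 0.0)) / (lo + np.where(zero, eps, 0.0))
    return pd.DataFrame(
        {
            "gene": common,
            "k_a": k_a,
            "k_b": k_b,
            "fold": ratio,
            "is_differential": ratio > fold,
            "direction": np.where(k_a >= k_b, "A-heavy", "B-heavy"),
            "zero_guarded": zero,
        }
    )


def node_euclidean_distance(
    net_a: WeightedNetwork, net_b: WeightedNetwork
) -> pd.DataFrame:
    """d(g) = sqrt(sum_j (a_gj - b_gj)^2) over common partners j != g."""
    common, a, b, _ = align_networks(net_a, net_b)
    d = np.sqrt(((a - b) ** 2).sum(axis=1))
    return pd.DataFrame({"gene": common, "euclidean_distance": d})


def pair_weight_difference(
    net_a: WeightedNetwork,
    net_b: WeightedNetwork,
    cycling_calls: pd.Series | dict,
    use_powered: bool = False,
) -> pd.DataFrame:
    """|w_A - w_B| per gene pair, summarized by cycling stratum.

    By default the difference is taken on the raw correlation scale
    (|cor| recovered as adjacency^(1/beta)); ``use_powered=True`` compares
    the soft-thresholded weights instead.  Strata are pairs with both /
    one / neither member a global cycler; medians per stratum plus
    two-sided rank-sum tests between strata.  The strata partition all
    pairs in the common universe.
    """
    common, a, b, _ = align_networks(net_a, net_b)
    if not use_powered:
        a = a ** (1.0 / net_a.beta)
        b = b ** (1.0 / net_b.beta)
    calls = pd.Series(cycling_calls).reindex(common)
    if calls.isna().any():
        raise ValueError("cycling calls missing for some common genes")
    is_c = calls.to_numpy().astype(bool)
    iu = np.triu_indices(len(common), k=1)
    delta = np.abs(a - b)[iu]
    n_cyc = is_c[iu[0]].astype(int) + is_c[iu[1]].astype(int)
    rows = []
    samples = {}
    for code, name in ((2, "both"), (1, "one"), (0, "neither")):
        vals = delta[n_cyc == code]
        samples[name] = vals
        rows.append({
            "stratum": name,
            "n_pairs": len(vals),
            "median_abs_delta": float(np.median(vals)) if len(vals) else float("nan"),
        })
    out = pd.DataFrame(rows)
    for x, y in (("both", "one"), ("one", "neither"), ("both", "neither")):
        if len(samples[x]) and len(samples[y]):
            p = float(stats.ranksums(samples[x], samples[y]).pvalue)
        else:
            p = float("nan")
        out.attrs[f"ranksum_{x}_vs_{y}"] = p
    return out


def module_jaccard(
    assign_a: ModuleAssignment,
    assign_b: ModuleAssignment,
    consensus_threshold: float = 0.3,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Jaccard index between every module pair; mutual-best consensus list.

    J(M_a, M_b) = |intersection| / |union| on gene sets.  A consensus pair
    is a mutual best match with J >= threshold.
    """
    mods_a, mods_b = assign_a.modules(), assign_b.modules()
    if not mods_a or not mods_b:
        raise ValueError("both assignments must contain modules")
    sets_a = {m: set(assign_a.members(m)) for m in mods_a}
    sets_b = {m: set(assign_b.members(m)) for m in mods_b}
    jac = np.zeros((len(mods_a), len(mods_b)))
    for i, ma in enumerate(mods_a):
        for j, mb in enumerate(mods_b):
            inter = len(sets_a[ma] & sets_b[mb])
            union = len(sets_a[ma] | sets_b[mb])
            jac[i, j] = inter / union if union else 0.0
    table = pd.DataFrame(jac, index=pd.Index(mods_a, name="module_a"),
                         columns=pd.Index(mods_b, name="module_b"))
    consensus = []
    best_for_a = jac.argmax(axis=1)
    best_for_b = jac.argmax(axis=0)
    for i, ma in enumerate(mods_a):
        j = best_for_a[i]
        if best_for_b[j] == i and jac[i, j] >= consensus_threshold:
            consensus.append((ma, mods_b[j], float(jac[i, j])))
    return table, consensus


def hub_subnetwork(
    net: WeightedNetwork,
    assignment: ModuleAssignment,
    module: str,
    top_n: int = 50,
) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """Top-``top_n`` module genes by intramodular connectivity, with the
    induced weighted subgraph.  Ties break lexicographically on gene id."""
    members = assignment.members(module)
    if not members:
        raise ValueError(f"module {module!r} is empty")
    idx = {n: i for i, n in enumerate(net.nodes)}
    missing = [g for g in members if g not in idx]
    if missing:
        raise ValueError(f"module genes absent from network: {missing[:5]}")
    rows = [idx[g] for g in members]
    sub = net.adjacency[np.ix_(rows, rows)]
    k_in = sub.sum(axis=1)
    order = sorted(range(len(members)), key=lambda i: (-k_in[i], members[i]))
    top = order[: min(top_n, len(members))]
    hub_genes = [members[i] for i in top]
    induced = sub[np.ix_(top, top)]
    scores = pd.DataFrame({
        "gene": [members[i] for i in order],
        "intramodular_connectivity": [k_in[i] for i in order],
        "is_hub": [i in set(top) for i in order],
    })
    return hub_genes, induced, scores
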