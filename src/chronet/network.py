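"""Soft-thresholded weighted co-expression networks and their topology.

Adjacency is the unsigned WGCNA form a_ij = |cor(x_i, x_j)|^beta with the
soft power beta = 16 by default.  Node- and network-level topology follows
the six fundamental network concepts (connectivity, clustering
coefficient, maximum adjacency ratio, density, centralization,
heterogeneity).  Modules come from average-linkage hierarchical clustering
of topological-overlap dissimilarity with a deterministic fixed-height
cut; module summaries (eigengene, mean expression) feed back into the
rhythm engine for module-level rhythmicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .atlas import ExpressionAtlas, assign_day_night
from .genesets import GeneSet
from .jtk import adjust_bh, build_references, rhythm_test_batch
from .cycling import enrichment_fisher

__all__ = [
    "WeightedNetwork",
    "build_network",
    "fundamental_concepts",
    "topological_overlap",
    "ModuleAssignment",
    "detect_modules",
    "module_rhythmicity",
    "module_set_enrichment",
    "day_night_topology",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


@dataclass
class WeightedNetwork:
    """Symmetric co-expression adjacency with weights in [0, 1], zero diagonal."""

    nodes: list[str]
    adjacency: np.ndarray
    beta: float
    scope: str = "all-samples"
    dropped_zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape mismatch")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("diagonal must be zero")
        if a.min() < 0 or a.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.adjacency = a

    @property
    def n(self) -> int:
        return len(self.nodes)

    def connectivity(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def build_network(
    expression: np.ndarray,
    nodes: list[str],
    beta: float = 16.0,
    scope: str = "all-samples",
) -> WeightedNetwork:
    """Unsigned soft-thresholded adjacency from a genes x samples matrix.

    Genes with zero variance across the selected samples are excluded and
    reported on the returned network.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = np.asarray(expression, dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need >= 3 samples in scope")
    sd = x.std(axis=1)
    # relative guard: numerically constant rows have sd at rounding scale
    keep = sd > 1e-10 * np.maximum(np.abs(x).max(axis=1), 1.0)
    dropped = [n for n, k in zip(nodes, keep) if not k]
    x = x[keep]
    kept_nodes = [n for n, k in zip(nodes, keep) if k]
    cor = np.corrcoef(x)
    np.clip(np.abs(cor, out=cor), 0.0, 1.0, out=cor)
    adj = cor**beta
    np.fill_diagonal(adj, 0.0)
    adj = (adj + adj.T) / 2.0  # enforce exact symmetry
    return WeightedNetwork(kept_nodes, adj, beta, scope, dropped)


def fundamental_concepts(net: WeightedNetwork) -> tuple[pd.DataFrame, dict]:
    """The six fundamental network concepts.

    Node level: connectivity k_i = sum_j a_ij; clustering coefficient
    c_i = (sum_{j!=k} a_ij a_jk a_ki) / (k_i^2 - sum_j a_ij^2); maximum
    adjacency ratio MAR_i = sum_j a_ij^2 / k_i.  Network level: density
    = sum_i k_i / (n (n-1)); centralization = n/(n-2) * (max k/(n-1) -
    density); heterogeneity = sd(k)/mean(k) (population sd).  Isolated
    nodes get MAR and clustering coefficient 0 (flagged).
    """
    a = net.adjacency
    n = net.n
    if n < 3:
        raise ValueError("need >= 3 nodes")
    k = a.sum(axis=1)
    sq = (a**2).sum(axis=1)
    triangle = np.einsum("ij,jk,ki->i", a, a, a)  # sum over j,k != i (diag zero)
    denom = k**2 - sq
    cluster = np.zeros_like(k)
    np.divide(triangle, denom, out=cluster, where=denom > 0)
    mar = np.zeros_like(k)
    np.divide(sq, k, out=mar, where=k > 0)
    density = k.sum() / (n * (n - 1))
    centralization = n / (n - 2) * (k.max() / (n - 1) - density)
    mean_k = k.mean()
    heterogeneity = k.std() / mean_k if mean_k > 0 else 0.0
    node_table = pd.DataFrame(
        {
            "node": net.nodes,
            "connectivity": k,
            "cluster_coefficient": cluster,
            "mar": mar,
            "isolated": k == 0,
        }
    )
    network_level = {
        "density": float(density),
        "centralization": float(centralization),
        "heterogeneity": float(heterogeneity),
        "median_connectivity": float(np.median(k)),
        "mean_connectivity": float(mean_k),
        "median_cluster_coefficient": float(np.median(cluster)),
        "median_mar": float(np.median(mar)),
        "n_nodes": n,
    }
    return node_table, network_level


def topological_overlap(net: WeightedNetwork) -> np.ndarray:
    """Unsigned TOM: w_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    L = A @ A (off-diagonal); diagonal set to 1."""
    a = net.adjacency
    k = a.sum(axis=1)
    l_mat = a @ a
    min_k = np.minimum(k[:, None], k[None, :])
    tom = (l_mat + a) / (min_k + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class ModuleAssignment:
    """Gene -> module labels plus per-module summary profiles per sample."""

    labels: pd.Series  # index gene, value module label or UNASSIGNED
    eigengenes: pd.DataFrame  # samples x modules
    mean_expression: pd.DataFrame  # samples x modules
    cut_height: float = float("nan")

    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _module_summaries(expression: np.ndarray, nodes: list[str],
                      labels: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    node_idx = {n: i for i, n in enumerate(nodes)}
    eig, mean_x = {}, {}
    for module in sorted(set(labels) - {UNASSIGNED}):
        members = [node_idx[g] for g in labels.index[labels == module]]
        sub = expression[members]  # genes x samples
        centered = sub - sub.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1, keepdims=True)
        z = np.zeros_like(centered)
        np.divide(centered, sd, out=z, where=sd > 0)
        # first principal component over samples, unit norm
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        pc = vt[0]
        # orient so that the average correlation with members is positive
        if np.mean(z @ pc) < 0:
            pc = -pc
        eig[module] = pc
        mean_x[module] = sub.mean(axis=0)
    return pd.DataFrame(eig), pd.DataFrame(mean_x)


def detect_modules(
    net: WeightedNetwork,
    expression: np.ndarray,
    min_module_size: int = 30,
    cut_height: float = 0.95,
) -> ModuleAssignment:
    """Average-linkage clustering of TOM dissimilarity, fixed-height cut.

    Clusters below ``min_module_size`` fall into the reserved
    ``unassigned`` label; surviving modules are named M1, M2, ... by
    decreasing size.  Deterministic: no random initialisation, gene input
    order only permutes labels.
    """
    tom = topological_overlap(net)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=pd.Index(net.nodes, name="gene"),
                       dtype=object)
    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_module_size]
    # stable module naming: decreasing size, ties by smallest member gene id
    def sort_key(c):
        members = [net.nodes[i] for i in np.nonzero(raw == c)[0]]
        return (-len(members), min(members))
    for rank, c in enumerate(sorted(big, key=sort_key), start=1):
        for i in np.nonzero(raw == c)[0]:
            labels.iloc[i] = f"M{rank}"
    if not big:
        import warnings

        warnings.warn("no module reaches min_module_size; all genes unassigned")
        return ModuleAssignment(labels, pd.DataFrame(), pd.DataFrame(), cut_height)
    eig, mean_x = _module_summaries(np.asarray(expression, dtype=float),
                                    net.nodes, labels)
    return ModuleAssignment(labels, eig, mean_x, cut_height)


def module_rhythmicity(
    assignment: ModuleAssignment,
    atlas: ExpressionAtlas,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rhythm-test each module's eigengene and mean-expression profile.

    Both summaries have one value per (organ, ZT) sample; values are
    grouped by ZT with organs as replicates, exactly as for single genes.
    BH runs across modules separately per variant; a module is rhythmic if
    either variant passes (the more sensitive of the two summaries).
    """
    modules = assignment.modules()
    if not modules:
        return pd.DataFrame(columns=["module", "variant", "p_raw", "p_adj",
                                     "phase", "is_rhythmic"])
    n_o, n_t = atlas.n_organs, atlas.n_times
    frames = []
    for variant, profile in (("eigengene", assignment.eigengenes),
                             ("mean_expression", assignment.mean_expression)):
        # samples are ordered organ-major (organ index slow, ZT fast)
        data = np.stack(
            [profile[m].to_numpy().reshape(n_o, n_t).T for m in modules]
        )  # modules x ZT x organs
        table = rhythm_test_batch(data, atlas.zt_times,
                                  period_hours=atlas.period_hours)
        table.insert(0, "module", modules)
        table.insert(1, "variant", variant)
        table["p_adj"] = adjust_bh(table["p_raw"])
        frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    passed = out[out["p_adj"] < alpha]["module"]
    out["is_rhythmic"] = out["module"].isin(set(passed))
    return out


def module_set_enrichment(
    assignment: ModuleAssignment,
    gene_set: GeneSet,
) -> pd.DataFrame:
    """Per-module Fisher enrichment of a gene set; BH across modules."""
    universe = list(assignment.labels.index)
    rows = []
    for module in assignment.modules():
        members = set(assignment.members(module))
        calls = {g: g in members for g in universe}
        res = enrichment_fisher(calls, gene_set, universe)
        rows.append({"module": module, "odds_ratio": res["odds_ratio"],
                     "p": res["p"], "degenerate": res["degenerate"]})
    out = pd.DataFrame(rows)
    out["q"] = adjust_bh(out["p"])
    return out


def day_night_topology(
    atlas: ExpressionAtlas,
    beta: float = 16.0,
    day_start: float = 0.0,
    day_end: float = 12.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[float, WeightedNetwork]]:
    """Per-ZT networks (genes x organs at that ZT) and day/night comparison.

    Builds one network per time point, computes the six concepts, then
    compares day-ZT vs night-ZT values of each index with a two-sided
    Wilcoxon rank-sum test.  Returns (per-ZT index table, comparison
    table, per-ZT networks).
    """
    per_zt = []
    nets = {}
    for t_i, zt in enumerate(atlas.zt_times):
        net = build_network(atlas.values[:, :, t_i], atlas.gene_ids, beta,
                            scope=f"ZT{int(zt):02d}")
        nets[float(zt)] = net
        _, level = fundamental_concepts(net)
        level["zt"] = float(zt)
        level["phase_class"] = assign_day_night(zt, day_start, day_end,
                                                atlas.period_hours)
        per_zt.append(level)
    per_zt_table = pd.DataFrame(per_zt)
    indices = ["median_connectivity", "density", "centralization",
               "heterogeneity", "median_cluster_coefficient", "median_mar"]
    comparisons = []
    day = per_zt_table[per_zt_table["phase_class"] == "day"]
    night = per_zt_table[per_zt_table["phase_class"] == "night"]
    for index in indices:
        if len(day) < 2 or len(night) < 2:
            import warnings

            warnings.warn("fewer than 2 ZTs in a phase class; comparison skipped")
            break
        res = stats.ranksums(night[index], day[index])
        comparisons.append({
            "index": index,
            "day_median": float(day[index].median()),
            "night_median": float(night[index].median()),
            "night_minus_day": float(night[index].median() - day[index].median()),
            "p": float(res.pvalue),
        })
    return per_zt_table, pd.DataFrame(comparisons), nets
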