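"""Global cycling gene detection from stacked multi-organ series.

A gene is a *global cycling gene* when the series formed by pooling every
organ's value at each time point (organs act as replicates within a ZT
group) passes the rhythm test at BH-adjusted p < alpha.  Robustness is
assessed by leave-one-organ-out reruns; phases are summarized per organ and
compared with the global phase; gene-set enrichment uses two-sided Fisher
exact tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ExpressionAtlas
from .genesets import GeneSet
from .jtk import GroupedSeries, adjust_bh, build_references, rhythm_test_batch

__all__ = [
    "stack_by_time",
    "detect_global_cycling",
    "per_organ_rhythms",
    "leave_one_out",
    "circular_median",
    "phase_summary",
    "enrichment_fisher",
]


def stack_by_time(atlas: ExpressionAtlas) -> dict[str, GroupedSeries]:
    """One grouped series per gene: group t holds the organ values at ZT t.

    Organ order within every group is the atlas organ order, identical
    across genes.
    """
    return {
        gene: GroupedSeries(atlas.zt_times, list(atlas.values[g_i].T),
                            atlas.period_hours)
        for g_i, gene in enumerate(atlas.gene_ids)
    }


def detect_global_cycling(
    atlas: ExpressionAtlas,
    alpha: float = 0.05,
    references=None,
) -> pd.DataFrame:
    """Rhythm-test every stacked series; BH across genes; call at p_adj < alpha.

    Returns one row per gene: S, tau, p_raw, p_adj, period, phase,
    amplitude, regime, is_global_cycler.
    """
    if atlas.n_organs < 2:
        raise ValueError("need >= 2 organs for global cycling detection")
    # genes x ZT x organs: organs are the replicates within each time group
    data = np.transpose(atlas.values, (0, 2, 1))
    table = rhythm_test_batch(data, atlas.zt_times, references,
                              period_hours=atlas.period_hours)
    table.insert(0, "gene", atlas.gene_ids)
    table["p_adj"] = adjust_bh(table["p_raw"])
    table["is_global_cycler"] = table["p_adj"] < alpha
    return table


def per_organ_rhythms(
    atlas: ExpressionAtlas,
    alpha: float = 0.05,
    references=None,
) -> pd.DataFrame:
    """Per-(gene, organ) rhythm results with BH within each organ."""
    refs = references or build_references(atlas.zt_times,
                                          periods=(atlas.period_hours,))
    frames = []
    for o_i, organ in enumerate(atlas.organ_ids):
        table = rhythm_test_batch(atlas.values[:, o_i, :], atlas.zt_times, refs,
                                  period_hours=atlas.period_hours)
        table.insert(0, "gene", atlas.gene_ids)
        table.insert(1, "organ", organ)
        table["p_adj"] = adjust_bh(table["p_raw"])
        table["is_rhythmic"] = table["p_adj"] < alpha
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def leave_one_out(
    atlas: ExpressionAtlas,
    alpha: float = 0.05,
    references=None,
) -> pd.DataFrame:
    """Rerun global cycling detection with each organ removed in turn.

    Returns per gene the number of runs calling it, plus the summary flags
    ``called_half`` (called in >= half of the runs) and ``called_all``.
    """
    if atlas.n_organs < 3:
        raise ValueError("leave-one-out needs >= 3 organs")
    counts = np.zeros(atlas.n_genes, dtype=int)
    for organ in atlas.organ_ids:
        sub = atlas.drop_organ(organ)
        calls = detect_global_cycling(sub, alpha, references)["is_global_cycler"]
        counts += calls.to_numpy()
    n_runs = atlas.n_organs
    return pd.DataFrame(
        {
            "gene": atlas.gene_ids,
            "n_called": counts,
            "n_runs": n_runs,
            "called_half": counts * 2 >= n_runs,
            "called_all": counts == n_runs,
        }
    )


def circular_median(phases, period: float = 24.0) -> float:
    """Median direction on the circle: minimizer (among the data points) of
    the summed circular distances; ties break toward the smaller ZT."""
    ph = np.asarray(phases, dtype=float) % period
    if ph.size == 0:
        raise ValueError("no phases")
    diff = np.abs(ph[:, None] - ph[None, :])
    circ = np.minimum(diff, period - diff)
    costs = circ.sum(axis=1)
    order = np.lexsort((ph, costs))
    return float(ph[order[0]])


def phase_summary(
    global_table: pd.DataFrame,
    organ_table: pd.DataFrame,
    period: float = 24.0,
) -> tuple[pd.DataFrame, float]:
    """Global phase vs per-organ circular-median phase for each cycler.

    Only organs where the gene is per-organ rhythmic contribute; genes
    rhythmic in zero organs are excluded from the concordance (counted in
    the output).  The concordance is the Pearson r on the linear ZT scale
    (the field's plotting convention; the circular caveat applies near the
    period boundary).
    """
    cyclers = global_table[global_table["is_global_cycler"]]
    rhythmic = organ_table[organ_table["is_rhythmic"]]
    by_gene = dict(list(rhythmic.groupby("gene")))
    rows = []
    for _, row in cyclers.iterrows():
        sub = by_gene.get(row["gene"])
        if sub is None or len(sub) == 0:
            rows.append((row["gene"], row["phase"], np.nan, 0))
            continue
        med = circular_median(sub["phase"].to_numpy(), period)
        rows.append((row["gene"], row["phase"], med, len(sub)))
    table = pd.DataFrame(
        rows, columns=["gene", "global_phase", "median_organ_phase", "n_rhythmic_organs"]
    )
    usable = table.dropna(subset=["median_organ_phase"])
    if len(usable) >= 2 and usable["global_phase"].std() > 0 and usable["median_organ_phase"].std() > 0:
        r = float(stats.pearsonr(usable["global_phase"], usable["median_organ_phase"])[0])
    else:
        r = float("nan")
    return table, r


def enrichment_fisher(
    calls: pd.Series | dict,
    gene_set: GeneSet,
    background: list[str],
) -> dict:
    """Two-sided Fisher exact test of set membership vs a boolean call.

    Returns the 2x2 table counts, the conditional-MLE odds ratio, and the
    two-sided p.  BH across a batch of sets is the caller's job (see
    :func:`chronet.jtk.adjust_bh`).
    """
    background = list(background)
    in_set = gene_set.genes & set(background)
    if not in_set:
        raise ValueError(f"gene set {gene_set.label!r} is disjoint from the background")
    calls = pd.Series(calls)
    called = {g for g in background if bool(calls.get(g, False))}
    a = len(in_set & called)
    b = len(in_set - called)
    c = len(called - in_set)
    d = len(background) - a - b - c
    table = np.array([[a, b], [c, d]])
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        return {"table": table, "odds_ratio": float("nan"), "p": 1.0,
                "degenerate": True}
    res = stats.fisher_exact(table, alternative="two-sided")
    odds = stats.contingency.odds_ratio(table).statistic
    return {"table": table, "odds_ratio": float(odds), "p": float(res.pvalue),
            "degenerate": False}
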