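"""Synthetic multi-organ circadian atlas and interactome with known truth.

The generator emulates the statistical structure of a body-wide circadian
expression atlas: organ-specific log-normal baselines; a planted fraction
of *global cyclers* (one cosine phase per gene shared by every organ, drawn
from a bimodal von Mises mixture peaked at noon/midnight ZT06 and ZT18);
*organ cyclers* rhythmic only in a random organ subset with organ-specific
phases; arrhythmic *flat* genes; gene pairs whose cross-organ correlation
oscillates over time, via an organ-level latent factor carried with a
constant loading by one member and a cosine-modulated loading by the other;
co-expression modules built on shared organ latents; and an optional
body-wide organ factor whose loading is amplified at night (planting
day/night network dimorphism).  Expression is clipped at zero (FPKM-like
non-negativity) and the clip rate is reported.

Every random draw flows from one integer seed through named substreams, so
runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .atlas import ExpressionAtlas
from .genesets import EdgeList

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_atlas",
    "InteractomeTruth",
    "simulate_interactome",
]


@dataclass(frozen=True)
class ModuleSpec:
    """Plan for one planted co-expression module."""

    size: int
    within_correlation: float = 0.6
    rhythmic: bool = False
    phase: float | None = None  # shared peak ZT if rhythmic


@dataclass
class SimulationConfig:
    """All knobs of the atlas generator (seed mandatory, no implicit entropy).

    Defaults describe a desk-scale study: 20 organs sampled every 2 h over
    one 24 h cycle, cosine amplitude twice the observation noise, 20%
    global cyclers and 10% organ-restricted cyclers.
    """

    n_genes: int = 1000
    n_organs: int = 20
    zt_times: tuple = tuple(range(0, 24, 2))
    period_hours: float = 24.0
    fraction_global_cyclers: float = 0.2
    fraction_organ_cyclers: float = 0.1
    amplitude: float = 2.0
    amplitude_organ_sd: float = 0.0  # log-sd of per-(gene, organ) rhythm strength
    noise_sd: float = 1.0
    baseline_log_mean: float = 1.6
    baseline_log_sd: float = 0.3
    organ_log_sd: float = 0.2
    organ_cycler_organ_fraction: float = 0.3
    phase_peaks: tuple = (6.0, 18.0)  # noon / midnight bimodality
    phase_kappa: float = 4.0
    n_coupled_pairs: int = 0
    coupling_strength: float = 2.0
    coupling_class_mix: tuple = (0.5, 0.3, 0.2)  # both / one / neither cycler
    module_plan: tuple = ()
    shared_factor_strength: float = 0.0
    night_amplification: float = 0.0
    night_peak: float = 18.0
    # phase-modulated coupling of global cyclers to the shared organ factor:
    # loading(g, t) = coupling * (1 + depth * cos(2*pi*(t - phi_g)/period)).
    # Because covariances of pure cosines are 12 h-periodic, this is the
    # mechanism that lets rhythmic genes rewire between noon and midnight.
    cycler_factor_coupling: float = 0.0
    cycler_factor_mod_depth: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.fraction_global_cyclers, self.fraction_organ_cyclers)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class fractions must lie in [0,1] and sum <= 1")
        if self.n_genes <= 0 or self.n_organs <= 0 or len(self.zt_times) < 4:
            raise ValueError("counts must be positive; need >= 4 time points")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if sum(m.size for m in self.module_plan) > self.n_genes:
            raise ValueError("module plan exceeds gene count")
        if abs(sum(self.coupling_class_mix) - 1.0) > 1e-9:
            raise ValueError("coupling_class_mix must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth for one simulated atlas; covers every gene exactly once."""

    gene_class: dict[str, str]  # global_cycler | organ_cycler | flat
    true_phase: dict[str, float]
    true_amplitude: dict[str, float]
    organ_sets: dict[str, list[str]]  # organ cyclers -> rhythmic organs
    coupled_pairs: list[dict]  # gene_a, gene_b, psi, stratum
    module_membership: dict[str, str]
    clip_fraction: float = 0.0

    def genes_of_class(self, label: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == label]


def _substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _mixture_phases(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    which = rng.random(n) < 0.5
    mus = np.where(which, cfg.phase_peaks[0], cfg.phase_peaks[1])
    angles = rng.vonmises(2 * np.pi * mus / cfg.period_hours, cfg.phase_kappa)
    return (angles % (2 * np.pi)) * cfg.period_hours / (2 * np.pi)


def simulate_atlas(config: SimulationConfig) -> tuple[ExpressionAtlas, GroundTruth]:
    """Generate one atlas plus its ground truth (deterministic in the seed)."""
    config.validate()
    rngs = _substreams(
        config.seed,
        ["class", "phase", "baseline", "noise", "coupling", "module", "factor"],
    )
    n_g, n_o = config.n_genes, config.n_organs
    zt = np.asarray(config.zt_times, dtype=float)
    n_t = len(zt)
    period = config.period_hours
    genes = [f"G{i:05d}" for i in range(n_g)]
    organs = [f"ORG{j:02d}" for j in range(n_o)]

    # class assignment on a shuffled gene order
    n_gc = int(round(config.fraction_global_cyclers * n_g))
    n_oc = int(round(config.fraction_organ_cyclers * n_g))
    perm = rngs["class"].permutation(n_g)
    classes = np.array(["flat"] * n_g, dtype=object)
    classes[perm[:n_gc]] = "global_cycler"
    classes[perm[n_gc : n_gc + n_oc]] = "organ_cycler"

    # baselines: organ-level log-mean plus per-(gene, organ) spread
    organ_mu = rngs["baseline"].normal(config.baseline_log_mean, config.organ_log_sd, n_o)
    base = np.exp(
        organ_mu[None, :]
        + rngs["baseline"].normal(0.0, config.baseline_log_sd, (n_g, n_o))
    )  # genes x organs

    phases = _mixture_phases(rngs["phase"], n_g, config)
    cos_t = lambda phi: np.cos(2 * np.pi * (zt[None, :] - np.asarray(phi)[:, None]) / period)

    values = base[:, :, None] + rngs["noise"].normal(0.0, config.noise_sd, (n_g, n_o, n_t))

    # organ-dependent rhythm strength: mean-one log-normal jitter per
    # (gene, organ), so rhythmic genes rewire their cross-organ
    # co-expression over the day while the population amplitude stays put
    sa = config.amplitude_organ_sd
    amp_jitter = np.exp(
        rngs["baseline"].normal(-0.5 * sa**2, sa, (n_g, n_o))
    ) if sa > 0 else np.ones((n_g, n_o))

    true_amp = np.zeros(n_g)
    organ_sets: dict[str, list[str]] = {}
    is_gc = classes == "global_cycler"
    true_amp[is_gc] = config.amplitude
    values[is_gc] += (
        config.amplitude * amp_jitter[is_gc, :, None] * cos_t(phases[is_gc])[:, None, :]
    )

    oc_idx = np.nonzero(classes == "organ_cycler")[0]
    n_rhythmic_organs = max(1, int(round(config.organ_cycler_organ_fraction * n_o)))
    for gi in oc_idx:
        organs_gi = rngs["class"].choice(n_o, size=n_rhythmic_organs, replace=False)
        organ_phases = _mixture_phases(rngs["phase"], n_rhythmic_organs, config)
        values[gi, organs_gi, :] += config.amplitude * amp_jitter[gi, organs_gi, None] * np.cos(
            2 * np.pi * (zt[None, :] - organ_phases[:, None]) / period
        )
        organ_sets[genes[gi]] = sorted(organs[j] for j in organs_gi)
        true_amp[gi] = config.amplitude

    # coupled pairs: one member loads the pair latent constantly, the other
    # with a cosine-modulated loading, so the cross-organ correlation is
    # 24 h-periodic and peaks at the coupling phase psi
    coupled: list[dict] = []
    if config.n_coupled_pairs:
        pool = {
            "both": list(np.nonzero(is_gc)[0]),
            "one": list(np.nonzero(is_gc)[0]),
            "neither": list(np.nonzero(classes == "flat")[0]),
        }
        flat_pool = list(np.nonzero(classes == "flat")[0])
        rng = rngs["coupling"]
        rng.shuffle(pool["both"])
        rng.shuffle(flat_pool)
        strata = rng.choice(
            ["both", "one", "neither"], size=config.n_coupled_pairs,
            p=list(config.coupling_class_mix),
        )
        used: set[int] = set()

        def take(candidates):
            while candidates:
                i = candidates.pop()
                if i not in used:
                    used.add(i)
                    return i
            raise ValueError("infeasible config: not enough genes for coupled pairs")

        gc_pool = pool["both"]
        for stratum in strata:
            if stratum == "both":
                a, b = take(gc_pool), take(gc_pool)
            elif stratum == "one":
                a, b = take(gc_pool), take(flat_pool)
            else:
                a, b = take(flat_pool), take(flat_pool)
            psi = rng.uniform(0, period)
            latent = rng.normal(0.0, 1.0, n_o)
            mod = np.cos(2 * np.pi * (zt - psi) / period)
            values[a] += config.coupling_strength * latent[:, None]
            values[b] += config.coupling_strength * latent[:, None] * mod[None, :]
            coupled.append(
                {"gene_a": genes[a], "gene_b": genes[b], "psi": psi, "stratum": stratum}
            )

    # planted modules: shared organ latent per module; rhythmic modules also
    # align their members' phases to the module phase
    membership: dict[str, str] = {}
    if config.module_plan:
        rng = rngs["module"]
        gc_free = [i for i in np.nonzero(is_gc)[0] if genes[i] not in
                   {p["gene_a"] for p in coupled} | {p["gene_b"] for p in coupled}]
        flat_free = [i for i in np.nonzero(classes == "flat")[0] if genes[i] not in
                     {p["gene_a"] for p in coupled} | {p["gene_b"] for p in coupled}]
        rng.shuffle(gc_free)
        rng.shuffle(flat_free)
        # unshared per-gene variance across samples: observation noise plus
        # the per-gene baseline spread over organs
        resid_var = config.noise_sd**2 + float(np.mean(base.var(axis=1)))
        for m_i, spec in enumerate(config.module_plan):
            label = f"M{m_i + 1}"
            src = gc_free if spec.rhythmic else flat_free
            if len(src) < spec.size:
                raise ValueError(f"module plan infeasible for {label}")
            members = [src.pop() for _ in range(spec.size)]
            c = spec.within_correlation
            lam = np.sqrt(c / (1.0 - c) * resid_var)
            latent = rng.normal(0.0, 1.0, n_o)
            for gi in members:
                values[gi] += lam * latent[:, None]
                membership[genes[gi]] = label
                if spec.rhythmic and spec.phase is not None:
                    # re-align the member's rhythm to the module phase
                    jit = config.amplitude * amp_jitter[gi, :, None]
                    values[gi] -= jit * np.cos(
                        2 * np.pi * (zt[None, :] - phases[gi]) / period
                    )
                    values[gi] += jit * np.cos(
                        2 * np.pi * (zt[None, :] - spec.phase) / period
                    )
                    phases[gi] = spec.phase

    # body-wide organ factor with night-amplified loading (dimorphism)
    w = rngs["factor"].normal(0.0, 1.0, n_o)
    if config.shared_factor_strength > 0:
        loading = config.shared_factor_strength * (
            1.0
            + config.night_amplification
            * np.cos(2 * np.pi * (zt - config.night_peak) / period)
        )
        values += (w[:, None] * loading[None, :])[None, :, :]
    if config.cycler_factor_coupling > 0:
        depth = config.cycler_factor_mod_depth
        mod = 1.0 + depth * cos_t(phases[is_gc])  # cyclers x times
        values[is_gc] += (
            config.cycler_factor_coupling * w[None, :, None] * mod[:, None, :]
        )

    clipped = values < 0
    clip_fraction = float(clipped.mean())
    values = np.clip(values, 0.0, None)

    atlas = ExpressionAtlas(
        gene_ids=genes,
        organ_ids=organs,
        zt_times=zt,
        values=values,
        period_hours=period,
    )
    truth = GroundTruth(
        gene_class={g: c for g, c in zip(genes, classes)},
        true_phase={
            g: float(phases[i]) if classes[i] != "flat" else float("nan")
            for i, g in enumerate(genes)
        },
        true_amplitude={g: float(true_amp[i]) for i, g in enumerate(genes)},
        organ_sets=organ_sets,
        coupled_pairs=coupled,
        module_membership=membership,
        clip_fraction=clip_fraction,
    )
    return atlas, truth


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

@dataclass
class InteractomeTruth:
    """Planted structure on a synthetic interactome."""

    modules: dict[str, list[str]]  # label -> connected node set
    proximal_pairs: list[dict]  # label, set_a, set_b, max_hops
    augmented_edges: int = 0


def _grow_connected(graph: nx.Graph, rng: np.random.Generator, size: int,
                    start: str | None = None) -> list[str]:
    """Random BFS-style growth of a connected node set (induced connected)."""
    nodes = list(graph.nodes)
    if start is None:
        start = nodes[int(rng.integers(len(nodes)))]
    chosen = {start}
    frontier = set(graph.neighbors(start))
    while len(chosen) < size:
        if not frontier:
            raise ValueError("cannot grow a connected module of the requested size")
        pick = sorted(frontier)[int(rng.integers(len(frontier)))]
        chosen.add(pick)
        frontier |= set(graph.neighbors(pick))
        frontier -= chosen
    return sorted(chosen)


def simulate_interactome(
    n_nodes: int = 500,
    model: str = "scale-free",
    attachment: int = 3,
    er_p: float = 0.02,
    planted_module_sizes: tuple = (),
    planted_pairs: tuple = (),  # tuples (size_a, size_b, max_hops)
    seed: int = 0,
) -> tuple[EdgeList, nx.Graph, InteractomeTruth]:
    """Generate a connected interactome with planted modules and set pairs.

    ``model`` is ``"scale-free"`` (preferential attachment) or ``"ER"``
    (Erdos-Renyi with edge probability ``er_p``).  Connectivity is enforced
    by adding one augmenting edge per extra component (count reported).
    Planted modules are grown so that their induced subgraphs are connected;
    planted proximal set pairs are grown with set B seeded within
    ``max_hops`` of set A.
    """
    for size in planted_module_sizes:
        if size >= n_nodes:
            raise ValueError("planted module size must be < n_nodes")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if model == "scale-free":
        g0 = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(seed) % (2**31))
    elif model == "ER":
        g0 = nx.gnp_random_graph(n_nodes, er_p, seed=int(seed) % (2**31))
    else:
        raise ValueError(f"unknown model {model!r}")
    mapping = {i: f"N{i:05d}" for i in g0.nodes}
    graph = nx.relabel_nodes(g0, mapping)

    augmented = 0
    comps = sorted(nx.connected_components(graph), key=len, reverse=True)
    for comp in comps[1:]:
        a = sorted(comp)[0]
        b = sorted(comps[0])[0]
        graph.add_edge(a, b)
        augmented += 1

    truth = InteractomeTruth(modules={}, proximal_pairs=[], augmented_edges=augmented)
    for m_i, size in enumerate(planted_module_sizes):
        members = _grow_connected(graph, rng, size)
        truth.modules[f"DM{m_i + 1}"] = members
    for p_i, (size_a, size_b, hops) in enumerate(planted_pairs):
        set_a = _grow_connected(graph, rng, size_a)
        ring = set(set_a)
        for _ in range(hops):
            ring |= {nb for n in ring for nb in graph.neighbors(n)}
        candidates = sorted(ring - set(set_a))
        if len(candidates) < size_b:
            raise ValueError("hop neighbourhood too small for the planted pair")
        pick = rng.choice(len(candidates), size=size_b, replace=False)
        set_b = sorted(candidates[i] for i in pick)
        truth.proximal_pairs.append(
            {"label": f"PP{p_i + 1}", "set_a": set_a, "set_b": set_b, "max_hops": hops}
        )

    edges = EdgeList()
    for a, b in graph.edges:
        edges.add(a, b)
    return edges, graph, truth
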