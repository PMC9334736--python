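"""Network-medicine statistics: disease modules and gene-set proximity.

Evaluates the planted disease module's d_s against uniform random sets
on the interactome, its day/night contrast on the ZT06 vs ZT18
co-expression graphs, and the planted set pair's proximity d_AB against
degree-matched nulls.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import parse_args

from chronet import medicine
from chronet.atlas import read_atlas
from chronet.genesets import GeneSet, read_edge_list
from chronet.pipeline import write_table


def main():
    args = parse_args(__doc__)
    out = args.out
    graph = medicine.graph_from_edges(read_edge_list(out / "interactome.tsv"))
    truth = json.loads((out / "interactome_truth.json").read_text())

    module = GeneSet("planted_module", frozenset(truth["modules"]["DM1"]))
    dm = medicine.disease_module_significance(graph, module, n_perm=1000,
                                              seed=args.seed + 20)
    print(f"planted disease module: d_s = {dm['d_s']:.3f} vs null "
          f"{dm['null_mean']:.3f} +/- {dm['null_sd']:.3f} "
          f"(z = {dm['z']:.2f}, p = {dm['p_empirical']:.4g})")

    pair = truth["proximal_pairs"][0]
    prox = medicine.proximity_significance(
        graph, GeneSet("set_a", frozenset(pair["set_a"])),
        GeneSet("set_b", frozenset(pair["set_b"])), n_perm=1000,
        seed=args.seed + 21)
    print(f"planted proximal pair: d_AB = {prox['d_ab']:.3f} vs null "
          f"{prox['null_mean']:.3f} +/- {prox['null_sd']:.3f} "
          f"(z = {prox['z']:.2f}, p = {prox['p_empirical']:.4g})")

    # day/night disease-module contrast on thresholded co-expression graphs
    atlas = read_atlas(out / "atlas_dimorphic.tsv")
    g_day = medicine.build_unweighted_network(atlas, zt=6.0, r_threshold=0.8)
    g_night = medicine.build_unweighted_network(atlas, zt=18.0, r_threshold=0.8)
    print(f"ZT06 graph: {g_day.n} nodes; ZT18 graph: {g_night.n} nodes")
    # night-phase cyclers form a tight co-expression module only at night
    dtruth = pd.read_csv(out / "dimorphic_truth.tsv", sep="\t")
    night_phase = dtruth[(dtruth["class"] == "global_cycler")
                         & (abs(((dtruth["phase"] - 18) + 12) % 24 - 12) <= 3)]
    members = [g for g in night_phase["gene"]
               if g in set(g_day.nodes) and g in set(g_night.nodes)][:15]
    disease = GeneSet("night_phase_cyclers", frozenset(members))
    dn = medicine.day_night_module_difference(g_day, g_night, disease,
                                              n_perm=1000, seed=args.seed + 22)
    rows = [
        {"test": "disease_module", **{k: dm[k] for k in
                                      ("d_s", "null_mean", "null_sd", "z",
                                       "p_empirical")}},
        {"test": "proximity", "d_s": prox["d_ab"],
         "null_mean": prox["null_mean"], "null_sd": prox["null_sd"],
         "z": prox["z"], "p_empirical": prox["p_empirical"]},
    ]
    if dn["defined"]:
        print(f"day-night d_s difference: delta = {dn['delta']:.3f} "
              f"(p = {dn['p_empirical']:.4g})")
        rows.append({"test": "day_night_difference", "d_s": dn["delta"],
                     "null_mean": dn["null_mean"], "null_sd": dn["null_sd"],
                     "z": float("nan"), "p_empirical": dn["p_empirical"]})
    write_table(pd.DataFrame(rows), out / "network_medicine.tsv", "analysis")


if __name__ == "__main__":
    main()
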