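"""All-sample weighted co-expression network, modules, module rhythmicity.

Builds the beta = 16 unsigned network over all (organ, ZT) samples,
extracts modules from TOM dissimilarity, rhythm-tests each module's
eigengene and mean expression, and tests modules for enrichment of
global cycling genes.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import parse_args

from chronet import cycling, network
from chronet.atlas import read_atlas
from chronet.genesets import GeneSet
from chronet.pipeline import write_table


def main():
    args = parse_args(__doc__)
    out = args.out
    atlas = read_atlas(out / "atlas_modules.tsv")
    truth = pd.read_csv(out / "module_truth.tsv", sep="\t")
    gc = cycling.detect_global_cycling(atlas, alpha=0.05)

    expr = atlas.values.reshape(atlas.n_genes, -1)
    net = network.build_network(expr, atlas.gene_ids, beta=16.0)
    nodes, level = network.fundamental_concepts(net)
    write_table(nodes, out / "concepts_nodes.tsv", "analysis")
    write_table(pd.DataFrame([level]), out / "concepts_network.tsv", "analysis")
    print(f"all-sample network: density {level['density']:.3g}, "
          f"heterogeneity {level['heterogeneity']:.3g}")

    assign = network.detect_modules(net, expr)
    write_table(assign.labels.rename("module").reset_index(),
                out / "modules.tsv", "analysis")
    print(f"{len(assign.modules())} modules detected "
          f"(planted: {truth['module'].replace('', pd.NA).nunique()})")
    for m in assign.modules():
        members = assign.members(m)
        top = truth.set_index("gene").reindex(members)["module"].fillna("")
        top = top[top != ""].mode()
        label = top.iloc[0] if len(top) else "none"
        print(f"  {m}: {len(members)} genes, majority planted label {label}")

    rhythm = network.module_rhythmicity(assign, atlas, alpha=0.05)
    write_table(rhythm, out / "module_rhythm.tsv", "analysis")
    rhythmic = rhythm.loc[rhythm["is_rhythmic"], "module"].unique()
    phases = rhythm[rhythm["variant"] == "eigengene"].set_index("module")["phase"]
    print(f"rhythmic modules: {list(rhythmic)}; eigengene phases "
          f"{phases.to_dict()}")

    cyclers = GeneSet("global_cyclers",
                      frozenset(gc.loc[gc["is_global_cycler"], "gene"]))
    enrich = network.module_set_enrichment(assign, cyclers)
    write_table(enrich, out / "module_cycler_enrichment.tsv", "analysis")
    hits = enrich[(enrich["q"] < 0.05) & (enrich["odds_ratio"] > 1)]
    print(f"modules enriched for global cycling genes: {list(hits['module'])}")


if __name__ == "__main__":
    main()
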