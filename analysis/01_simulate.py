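"""Generate the synthetic study: two atlases, an interactome, ground truth.

Writes the main multi-organ atlas (planted cyclers, coupled pairs,
modules), a dimorphic atlas with night-amplified organ coupling, and a
scale-free interactome with a planted disease module and proximal set
pair.  Everything downstream reads these files.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import (
    comparison_atlas_config,
    dimorphic_atlas_config,
    main_atlas_config,
    module_atlas_config,
    parse_args,
)

from chronet.atlas import write_atlas
from chronet.simulate import simulate_atlas, simulate_interactome


def main():
    args = parse_args(__doc__)
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    atlas, truth = simulate_atlas(main_atlas_config(args.seed))
    write_atlas(atlas, out / "atlas.tsv")
    pd.DataFrame({
        "gene": atlas.gene_ids,
        "class": [truth.gene_class[g] for g in atlas.gene_ids],
        "phase": [truth.true_phase[g] for g in atlas.gene_ids],
        "module": [truth.module_membership.get(g, "") for g in atlas.gene_ids],
    }).to_csv(out / "ground_truth.tsv", sep="\t", index=False,
              float_format="%.6g")
    pd.DataFrame(truth.coupled_pairs).to_csv(
        out / "coupled_pairs.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"main atlas: {atlas.n_genes} genes x {atlas.n_organs} organs x "
          f"{atlas.n_times} ZT; clip fraction {truth.clip_fraction:.4f}")

    matlas, mtruth = simulate_atlas(module_atlas_config(args.seed))
    write_atlas(matlas, out / "atlas_modules.tsv")
    pd.DataFrame({
        "gene": matlas.gene_ids,
        "module": [mtruth.module_membership.get(g, "") for g in matlas.gene_ids],
        "phase": [mtruth.true_phase[g] for g in matlas.gene_ids],
    }).to_csv(out / "module_truth.tsv", sep="\t", index=False,
              float_format="%.6g")
    print(f"module atlas: {matlas.n_genes} genes x {matlas.n_organs} organs, "
          f"3 planted modules")

    datlas, dtruth = simulate_atlas(dimorphic_atlas_config(args.seed))
    write_atlas(datlas, out / "atlas_dimorphic.tsv")
    pd.DataFrame({
        "gene": datlas.gene_ids,
        "class": [dtruth.gene_class[g] for g in datlas.gene_ids],
        "phase": [dtruth.true_phase[g] for g in datlas.gene_ids],
    }).to_csv(out / "dimorphic_truth.tsv", sep="\t", index=False,
              float_format="%.6g")
    print(f"dimorphic atlas: {datlas.n_genes} genes, night-amplified coupling")

    catlas, ctruth = simulate_atlas(comparison_atlas_config(args.seed))
    write_atlas(catlas, out / "atlas_comparison.tsv")
    pd.DataFrame({
        "gene": catlas.gene_ids,
        "class": [ctruth.gene_class[g] for g in catlas.gene_ids],
    }).to_csv(out / "comparison_truth.tsv", sep="\t", index=False)
    print(f"comparison atlas: {catlas.n_genes} genes, phase-modulated "
          f"cycler coupling")

    edges, _, itruth = simulate_interactome(
        n_nodes=800, planted_module_sizes=(12,), planted_pairs=((10, 10, 1),),
        seed=args.seed + 2)
    with open(out / "interactome.tsv", "w") as fh:
        for a, b in sorted(edges.pairs):
            fh.write(f"{a}\t{b}\n")
    with open(out / "interactome_truth.json", "w") as fh:
        json.dump({"modules": itruth.modules,
                   "proximal_pairs": itruth.proximal_pairs}, fh, indent=2)
    print(f"interactome: {len(edges)} edges, planted module of "
          f"{len(itruth.modules['DM1'])} nodes")


if __name__ == "__main__":
    main()
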