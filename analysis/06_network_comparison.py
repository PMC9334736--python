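"""Compare the noon (ZT06) and midnight (ZT18) co-expression networks.

Differential connectivity (>2-fold), per-node Euclidean distance, raw
|cor| pair-weight differences stratified by cycling status, and module
Jaccard similarity between the two scopes — all on the dimorphic atlas.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import parse_args

from chronet import compare, cycling, network
from chronet.atlas import read_atlas
from chronet.pipeline import write_table


def main():
    args = parse_args(__doc__)
    out = args.out
    atlas = read_atlas(out / "atlas_comparison.tsv")
    gc = cycling.detect_global_cycling(atlas, alpha=0.05)
    calls = pd.Series(gc["is_global_cycler"].to_numpy(), index=gc["gene"])

    t6 = int(np.nonzero(atlas.zt_times == 6.0)[0][0])
    t18 = int(np.nonzero(atlas.zt_times == 18.0)[0][0])
    net6 = network.build_network(atlas.values[:, :, t6], atlas.gene_ids,
                                 beta=16.0, scope="ZT06")
    net18 = network.build_network(atlas.values[:, :, t18], atlas.gene_ids,
                                  beta=16.0, scope="ZT18")

    diff = compare.differential_connectivity(net6, net18, fold=2.0)
    write_table(diff, out / "differential_connectivity.tsv", "analysis")
    frac = diff["is_differential"].mean()
    among = calls.reindex(diff.loc[diff["is_differential"], "gene"]).mean()
    print(f"{100 * frac:.1f}% of genes are >2-fold differentially connected "
          f"between ZT06 and ZT18; {100 * among:.1f}% of those are global "
          f"cycling genes")

    eucl = compare.node_euclidean_distance(net6, net18).set_index("gene")
    write_table(eucl.reset_index(), out / "node_euclidean.tsv", "analysis")
    cyc = eucl.loc[calls[calls].index.intersection(eucl.index),
                   "euclidean_distance"]
    non = eucl.loc[calls[~calls].index.intersection(eucl.index),
                   "euclidean_distance"]
    from scipy import stats

    print(f"median node distance: cyclers {cyc.median():.4g} vs others "
          f"{non.median():.4g} (rank-sum p = {stats.ranksums(cyc, non).pvalue:.2g})")

    delta = compare.pair_weight_difference(net6, net18, calls)
    write_table(delta, out / "pair_delta_summary.tsv", "analysis")
    print("median |delta cor| by stratum:",
          dict(zip(delta["stratum"], delta["median_abs_delta"].round(4))))

    # module similarity across scopes, on the module-bearing atlas where
    # per-ZT networks carry detectable block structure
    matlas = read_atlas(out / "atlas_modules.tsv")
    m6 = int(np.nonzero(matlas.zt_times == 6.0)[0][0])
    m18 = int(np.nonzero(matlas.zt_times == 18.0)[0][0])
    a6 = network.detect_modules(
        network.build_network(matlas.values[:, :, m6], matlas.gene_ids,
                              beta=16.0, scope="ZT06"),
        matlas.values[:, :, m6], min_module_size=15)
    a18 = network.detect_modules(
        network.build_network(matlas.values[:, :, m18], matlas.gene_ids,
                              beta=16.0, scope="ZT18"),
        matlas.values[:, :, m18], min_module_size=15)
    if a6.modules() and a18.modules():
        jac, consensus = compare.module_jaccard(a6, a18)
        write_table(jac.reset_index(), out / "module_jaccard.tsv", "analysis")
        print(f"{len(a6.modules())} ZT06 and {len(a18.modules())} ZT18 "
              f"modules; {len(consensus)} consensus pairs (mutual best, "
              f"J >= 0.3)")
    else:
        print("too few per-ZT modules for a Jaccard comparison")


if __name__ == "__main__":
    main()
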