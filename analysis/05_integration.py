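#!/usr/bin/env python
"""Integrative stage: PCA of the ion matrices, genotype pooling, gene
co-expression network at r > 0.7 / p < 0.01, and signed correlation of
pooled expression with the biochemical stage trends.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import silhouette_score

from pomewall.integration import (
    build_network,
    correlate_biochem_transcript,
    pca,
    pool_genotypes,
)
from pomewall.transcriptome_stats import ExpressionMatrix, quantile_normalize

SIM = Path(__file__).resolve().parents[1] / "scratch" / "simulated"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for digest in ("mannanase", "glucanase"):
        mat = pd.read_csv(OUT / f"ion_matrix_{digest}.tsv", sep="\t",
                          index_col=[0, 1, 2, 3])
        res = pca(mat)
        res.scores.to_csv(OUT / f"pca_scores_{digest}.tsv", sep="\t")
        evr = res.explained_variance_ratio
        stages = mat.index.get_level_values("stage")
        early = stages.isin(["60DAF", "110DAF"])
        sil = silhouette_score(res.scores.to_numpy()[:, :1], early)
        print(f"{digest} ion PCA: PC1 {evr[0]:.0%}, PC2 {evr[1]:.0%} of variance; "
              f"early/mature silhouette on PC1 = {sil:.2f}")

    em = ExpressionMatrix.from_tsv(SIM / "expression.tsv", SIM / "samples.tsv")
    truth = pd.read_csv(SIM / "true_clusters.tsv", sep="\t", index_col=0)["cluster"]
    values = quantile_normalize(em.values)
    pooled = pool_genotypes(values, em.samples)
    planted = truth.index[truth != "flat"]

    net = build_network(pooled.loc[planted], r_min=0.7, p_max=0.01,
                        signed_mode="positive")
    net.to_edge_list().to_csv(SIM / "gene_network_edges_full.tsv", sep="\t", index=False)
    comps = [c for c in net.components() if len(c) > 1]
    pd.DataFrame({"component": range(1, len(comps) + 1),
                  "size": [len(c) for c in comps],
                  "members": ["," .join(sorted(c)[:6]) + ("..." if len(c) > 6 else "")
                              for c in comps]}).to_csv(
        OUT / "gene_network_components.tsv", sep="\t", index=False)
    print(f"gene network over {len(planted)} planted genes: "
          f"{net.graph.number_of_edges()} edges, component sizes "
          f"{sorted((len(c) for c in comps), reverse=True)[:4]} "
          f"(planted A and B groups should form the two large components)")

    reps = pd.read_csv(SIM / "composition_replicates.tsv", sep="\t",
                       header=[0, 1], index_col=0)
    reps.columns = reps.columns.set_names(["stage", "pool"])
    corr = correlate_biochem_transcript(reps, pooled.loc[planted])
    corr.to_csv(OUT / "biochem_transcript_correlations.tsv", sep="\t", index=False)
    corr = corr.merge(truth.rename("cluster"), left_on="gene", right_index=True)
    summary = (corr.groupby(["cluster", "variable"])["r"].median()
               .unstack().round(2))
    print("median gene-analyte correlation by planted cluster "
          "(A should be +Gal/+Man, -Xyl/-Fuc; B the opposite):")
    print(summary.to_string())


if __name__ == "__main__":
    main()
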