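#!/usr/bin/env python
"""The 2^3 factorial differential-expression stage on planted data.

Simulates the sex x genotype x organ matrix with four planted expression
patterns, runs per-probe factorial ANOVA + BH, applies the log2FC gates
(0.286 SNR, 0.094 practical), curates probe annotations, and reports PCA
variance and pattern-cluster recovery against the planted truth.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from fusionsplice.factorial_de import (
    DEConfig,
    call_differential,
    cluster_patterns,
    curate_probes,
    fit_factorial_anova,
    pca_on_significant,
    posthoc_pairwise,
)
from fusionsplice.synthetic_data import (
    ExpressionSpec,
    simulate_annotation,
    simulate_expression,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "factorial_de"
SEED = 1


def run_stage(replicates: int, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    spec = ExpressionSpec(replicates=replicates)
    matrix, design, truth = simulate_expression(spec, seed=SEED + 13)
    matrix.to_csv(outdir / "expression.tsv", sep="\t")
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    print(f"matrix: {matrix.shape[0]} probes x {matrix.shape[1]} samples "
          f"({design.groupby('genotype').size().min()} per genotype)")

    anova = fit_factorial_anova(matrix, design)
    posthoc = posthoc_pairwise(matrix, design)
    calls = call_differential(anova, posthoc, DEConfig())
    calls.to_csv(outdir / "differential_calls.tsv", sep="\t", index=False)

    sig_probes = calls.loc[calls["multivariate_significant"], "probe"].unique()
    diff_probes = calls.loc[calls["pairwise_differential"], "probe"].unique()
    robust_probes = calls.loc[calls["robust"], "probe"].unique()
    print(f"multivariate significant probes: {len(sig_probes)} "
          f"(200 planted among {matrix.shape[0]})")
    print(f"pairwise differential probes:    {len(diff_probes)}")
    print(f"robust (|log2FC| > 0.286):       {len(robust_probes)}")

    annotation = simulate_annotation(matrix.index, seed=SEED)
    curated, removed = curate_probes(list(sig_probes), annotation)
    print(f"curated single-gene significant probes: {len(curated)} "
          f"(removed {removed})")
    if len(sig_probes) >= 2:
        pca = pca_on_significant(matrix.loc[sig_probes])
        pd.DataFrame(
            {"component": [f"PC{i+1}" for i in range(len(pca.variance_pct))],
             "variance_pct": pca.variance_pct}
        ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
        print(f"PC1+PC2 variance over significant probes: "
              f"{pca.variance_pct[:2].sum():.0f}%")

    if len(curated) >= 8:
        lfc = anova.loc[curated, [c for c in anova.columns if c.startswith("lfc_")]]
        labels, summary = cluster_patterns(lfc, k=4)
        labels.to_frame().to_csv(outdir / "clusters.tsv", sep="\t")
        summary.to_csv(outdir / "cluster_summary.tsv", sep="\t")
        print("cluster log2FC summaries:")
        print(summary.to_string())
        ari_all = adjusted_rand_score(truth.loc[curated, "cluster"], labels)
        planted_mask = (truth.loc[curated, "cluster"] != "null").to_numpy()
        n_fp = int((~planted_mask).sum())
        print(f"adjusted Rand index vs planted patterns: {ari_all:.3f}")
        if n_fp and ari_all < 0.9:
            planted_probes = [p for p, keep in zip(curated, planted_mask) if keep]
            re_labels, _ = cluster_patterns(lfc.loc[planted_probes], k=4)
            ari_re = adjusted_rand_score(
                truth.loc[planted_probes, "cluster"], re_labels
            )
            print(f"  note: {n_fp} false-positive probes sit in the discovery "
                  f"set; their noise profiles dominate the fixed k=4 cut. "
                  f"Re-clustering the {len(planted_probes)} planted members "
                  f"alone gives ARI {ari_re:.3f}.")


def main() -> None:
    print("== study design (n = 2 per cell; 8 specimens per genotype) ==")
    print("   Welch post hoc at n = 2 has ~2 denominator df: the gate chain")
    print("   is deliberately conservative at this replication.")
    run_stage(2, OUT / "n2")
    print("\n== power-adequate replication (n = 4 per cell) ==")
    run_stage(4, OUT / "n4")


if __name__ == "__main__":
    main()
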