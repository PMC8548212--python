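#!/usr/bin/env python
"""Quantify the three isoform-discriminating junctions in short-read data.

Counts reads spanning SSR-E2, SINE-E2 and E1-E2 (8-nt overhangs) in
simulated cell-type samples, normalises to counts per locus FPKM, and
reports per-sample junction shares — the cell-type expression picture:
neurons dominated by the SINE junction, astrocytes purely reference,
progenitors mixed.
"""

from pathlib import Path

from fusionsplice.junction_quant import (
    count_junction_reads,
    isoform_share,
    junctions_from_model,
    normalize_counts,
)
from fusionsplice.synthetic_data import build_fixture_genome, simulate_junction_reads

OUT = Path(__file__).resolve().parent.parent / "results" / "junctions"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fixture = build_fixture_genome(seed=SEED)
    reads, truth = simulate_junction_reads(fixture, seed=SEED + 3)
    junctions = junctions_from_model(
        fixture.model, [("SSR", "E2"), ("SINE", "E2"), ("E1", "E2")]
    )

    counts = count_junction_reads(reads, junctions, fixture.model)
    norm = normalize_counts(counts, truth["gene_fpkm"])
    shares = isoform_share(norm)
    shares.to_csv(OUT / "junction_counts.tsv", sep="\t", index=False)

    print("junction counts per sample (raw / counts-per-FPKM / share):")
    for row in shares.itertuples():
        print(f"  {row.sample:10s} {row.junction:8s} raw={row.count:3d} "
              f"per_fpkm={row.normalized:6.2f} share={row.share:.2f}")
    print("\nplanted depths:", truth["depths"])


if __name__ == "__main__":
    main()
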