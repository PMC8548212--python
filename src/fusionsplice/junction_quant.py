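"""Short-read quantification of isoform-discriminating splice junctions.

Three junctions discriminate the locus' isoforms: SSR-E2 and SINE-E2 (the
fusion transcripts) versus E1-E2 (the reference).  A spliced short read
counts toward a junction iff its alignment jumps exactly from the donor
exon's last base to the acceptor exon's first base with at least
``min_overhang`` matched bases on each side.  Counts are normalised to
"counts per FPKM": the junction-spanning read count divided by the locus'
gene-level FPKM in that sample (an alternative per-kb-per-million scaling of
the junction count itself is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_model import GeneModel, ModelError


@dataclass(frozen=True)
class JunctionDef:
    """A named exon-exon junction with genomic edge coordinates (1-based)."""

    name: str
    donor: str
    acceptor: str
    donor_end: int      # last genomic base of the donor exon
    acceptor_start: int  # first genomic base of the acceptor exon
    transcript_breakpoint: int | None = None


def junctions_from_model(
    model: GeneModel, pairs: Sequence[tuple[str, str]]
) -> list[JunctionDef]:
    """Build junction definitions for donor/acceptor exon-id pairs."""
    out = []
    for donor, acceptor in pairs:
        if model.exon_index(donor) >= model.exon_index(acceptor):
            raise ModelError(f"junction {donor}-{acceptor}: donor must precede acceptor")
        d, a = model.exon(donor).interval, model.exon(acceptor).interval
        if model.strand == "+":
            out.append(JunctionDef(f"{donor}-{acceptor}", donor, acceptor, d.end, a.start))
        else:
            out.append(JunctionDef(f"{donor}-{acceptor}", donor, acceptor, d.start, a.end))
    return out


@dataclass
class SplicedRead:
    """A short-read alignment reduced to its genomic blocks (0-based half-open)."""

    read_id: str
    blocks: list[tuple[int, int]]
    mapq: int = 60


def _read_spans(read: SplicedRead, j: JunctionDef, min_overhang: int, strand: str) -> bool:
    # blocks are genome-forward; on '-' the genomically-left block is the acceptor
    for (s1, e1), (s2, e2) in zip(read.blocks, read.blocks[1:]):
        if strand == "+":
            if e1 == j.donor_end and s2 == j.acceptor_start - 1:
                if e1 - s1 >= min_overhang and e2 - s2 >= min_overhang:
                    return True
        else:
            if e1 == j.acceptor_start and s2 == j.donor_end - 1:
                if e1 - s1 >= min_overhang and e2 - s2 >= min_overhang:
                    return True
    return False


def count_junction_reads(
    reads_by_sample: Mapping[str, Iterable[SplicedRead]],
    junctions: Sequence[JunctionDef],
    model: GeneModel,
    min_overhang: int = 8,
    min_mapq: int = 0,
) -> pd.DataFrame:
    """Raw junction-spanning read counts, samples x junctions (long format).

    Each read increments a junction at most once; a short-insert read that
    crosses two junctions of the same isoform increments both.
    """
    known = set(model.exon_ids)
    for j in junctions:
        if j.donor not in known or j.acceptor not in known:
            raise ModelError(f"junction {j.name} references exons absent from the model")
    rows = []
    for sample, reads in reads_by_sample.items():
        counts = {j.name: 0 for j in junctions}
        for read in reads:
            if read.mapq < min_mapq:
                continue
            for j in junctions:
                if _read_spans(read, j, min_overhang, model.strand):
                    counts[j.name] += 1
        for name, c in counts.items():
            rows.append({"sample": sample, "junction": name, "count": c})
    return pd.DataFrame(rows)


def count_junction_reads_sam(
    sam_paths: Mapping[str, str],
    junctions: Sequence[JunctionDef],
    model: GeneModel,
    min_overhang: int = 8,
    min_mapq: int = 0,
) -> pd.DataFrame:
    """As :func:`count_junction_reads`, reading spliced SAM (N operations)."""
    import pysam

    def load(path: str) -> list[SplicedRead]:
        out = []
        with pysam.AlignmentFile(path, "r") as sam:
            for aln in sam:
                if aln.is_unmapped:
                    continue
                out.append(SplicedRead(aln.query_name, aln.get_blocks(), aln.mapping_quality))
        return out

    return count_junction_reads(
        {s: load(p) for s, p in sam_paths.items()}, junctions, model, min_overhang, min_mapq
    )


def read_junction_counts_tsv(path: str) -> pd.DataFrame:
    """Precomputed junction table: sample, junction, count."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "junction", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"junction TSV lacks columns: {sorted(missing)}")
    return df


def normalize_counts(
    counts: pd.DataFrame,
    gene_fpkm: Mapping[str, float],
    mode: str = "per_gene_fpkm",
    junction_span_kb: float | None = None,
    library_sizes: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Attach normalised values to raw junction counts.

    ``per_gene_fpkm`` (default): count / locus FPKM in that sample.
    ``per_kb_per_million``: count / span_kb / (library size / 1e6) — the
    alternative reading of the figure legend's units.
    Samples with FPKM 0 but nonzero counts are flagged and left NaN.
    """
    df = counts.copy()
    if mode == "per_gene_fpkm":
        fpkm = df["sample"].map(dict(gene_fpkm))
        if fpkm.isna().any():
            raise KeyError("missing gene FPKM for some samples")
        with np.errstate(divide="ignore", invalid="ignore"):
            df["normalized"] = np.where(
                fpkm > 0, df["count"] / fpkm, np.where(df["count"] == 0, 0.0, np.nan)
            )
        df["flag_zero_fpkm"] = (fpkm == 0) & (df["count"] > 0)
        df["gene_fpkm"] = fpkm
    elif mode == "per_kb_per_million":
        if junction_span_kb is None or library_sizes is None:
            raise ValueError("per_kb_per_million needs junction_span_kb and library_sizes")
        lib = df["sample"].map(dict(library_sizes))
        df["normalized"] = df["count"] / junction_span_kb / (lib / 1e6)
        df["library_size"] = lib
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return df


def isoform_share(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample junction proportions (sum to 1); all-zero samples flagged NaN."""
    df = counts.copy()
    totals = df.groupby("sample")["count"].transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["share"] = np.where(totals > 0, df["count"] / totals, np.nan)
    df["flag_all_zero"] = totals == 0
    return df
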