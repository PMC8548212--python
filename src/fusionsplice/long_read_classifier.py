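"""QC filtering and junction-based classification of long reads.

A long read supports an isoform only if its alignment to that isoform's
template crosses at least one exon-exon breakpoint with a minimum matched
overhang on both sides; alignments below a mapping-quality floor are
discarded.  Because candidate templates share their downstream exons, a read
can legitimately pass on several templates: it is assigned to the template
whose spanned-junction set strictly contains every other candidate's, and
flagged ambiguous when no such unique most-specific candidate exists.

Alignments can come from any aligner (SAM via pysam, or PAF), or from the
built-in :class:`AnchorMatcher`, an exact k-mer offset-voting placer that
tolerates substitution errors and keeps the whole pipeline free of external
aligner processes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .template_enum import IsoformTemplate


@dataclass
class LongRead:
    id: str
    sequence: str
    quality: Sequence[int] | None = None  # Phred scores, optional (CCS FASTA)

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    @property
    def mean_quality(self) -> float | None:
        if self.quality is None:
            return None
        return float(np.mean(self.quality))


@dataclass
class ReadFilterConfig:
    min_mean_quality: float = 10.0
    head_trim: int = 50
    min_length_full: int = 2000

    def __post_init__(self) -> None:
        if min(self.min_mean_quality, self.head_trim, self.min_length_full) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class QCResult:
    kept: list[LongRead]
    dropped: list[tuple[str, str]]  # (read id, reason)
    flagged_no_quality: list[str]


def qc_filter(reads: Iterable[LongRead], config: ReadFilterConfig | None = None) -> QCResult:
    """Trim read heads and drop reads whose mean Phred falls below the floor.

    Reads without quality strings pass the quality gate but are flagged, the
    common case for consensus FASTA input.
    """
    config = config or ReadFilterConfig()
    kept, dropped, flagged = [], [], []
    for read in reads:
        seq = read.sequence[config.head_trim :]
        qual = None if read.quality is None else list(read.quality[config.head_trim :])
        if not seq:
            dropped.append((read.id, "empty_after_trim"))
            continue
        if qual is not None and float(np.mean(qual)) < config.min_mean_quality:
            dropped.append((read.id, "low_quality"))
            continue
        if qual is None:
            flagged.append(read.id)
        kept.append(LongRead(read.id, seq, qual))
    return QCResult(kept, dropped, flagged)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    read_id: str
    template_id: str
    mapq: int
    blocks: list[tuple[int, int]]  # half-open spans in template coordinates
    read_length: int = 0

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError(
                    f"alignment {self.read_id}->{self.template_id}: blocks must be "
                    "sorted and non-overlapping"
                )


@dataclass
class ReadAssignment:
    read_id: str
    isoform_id: str | None
    spanned_junctions: frozenset[tuple[str, str]]
    full_length: bool
    reason: str  # pass | low_mapq | no_junction | ambiguous | too_short
    read_length: int = 0


def _spanned(
    aln: AlignmentRecord, template: IsoformTemplate, min_overhang: int
) -> frozenset[tuple[str, str]]:
    hits = []
    for j in template.junctions:
        lo, hi = j.breakpoint - min_overhang, j.breakpoint + min_overhang
        if any(s <= lo and e >= hi for s, e in aln.blocks):
            hits.append((j.donor, j.acceptor))
    return frozenset(hits)


def classify_alignment(
    aln: AlignmentRecord,
    template: IsoformTemplate,
    min_mapq: int = 20,
    min_overhang: int = 8,
) -> ReadAssignment:
    """Classify one alignment against one template.

    A junction is spanned iff a single aligned block covers
    [breakpoint - min_overhang, breakpoint + min_overhang).  The read is
    assigned iff MAPQ clears the floor and at least one junction is spanned.
    """
    if aln.template_id != template.id:
        raise KeyError(
            f"alignment targets {aln.template_id!r}, not template {template.id!r}"
        )
    if aln.mapq < min_mapq:
        return ReadAssignment(
            aln.read_id, None, frozenset(), False, "low_mapq", aln.read_length
        )
    spanned = _spanned(aln, template, min_overhang)
    if not spanned:
        return ReadAssignment(
            aln.read_id, None, frozenset(), False, "no_junction", aln.read_length
        )
    return ReadAssignment(
        aln.read_id, template.id, spanned, False, "pass", aln.read_length
    )


def resolve_read(
    alignments: Sequence[AlignmentRecord],
    templates: Mapping[str, IsoformTemplate],
    min_mapq: int = 20,
    min_overhang: int = 8,
) -> ReadAssignment:
    """Resolve all of one read's template alignments into a single call.

    Among templates that pass :func:`classify_alignment`, the winner must
    span a strict superset of every other candidate's junction set (junctions
    identified by donor/acceptor exon pair); equal or incomparable evidence
    yields ``ambiguous``.
    """
    if not alignments:
        raise ValueError("resolve_read needs at least one alignment")
    read_id = alignments[0].read_id
    read_length = max(a.read_length for a in alignments)
    calls = []
    reasons = []
    for aln in alignments:
        tpl = templates.get(aln.template_id)
        if tpl is None:
            raise KeyError(f"unknown template {aln.template_id!r}")
        call = classify_alignment(aln, tpl, min_mapq, min_overhang)
        (calls if call.reason == "pass" else reasons).append(call)
    if not calls:
        reason = "no_junction" if any(r.reason == "no_junction" for r in reasons) else "low_mapq"
        return ReadAssignment(read_id, None, frozenset(), False, reason, read_length)
    calls.sort(key=lambda c: len(c.spanned_junctions), reverse=True)
    best = calls[0]
    others = calls[1:]
    if all(
        c.spanned_junctions < best.spanned_junctions for c in others
    ):  # strict superset of every rival
        return ReadAssignment(
            read_id, best.isoform_id, best.spanned_junctions, False, "pass", read_length
        )
    return ReadAssignment(read_id, None, frozenset(), False, "ambiguous", read_length)


def summarize_support(
    assignments: Iterable[ReadAssignment],
    templates: Mapping[str, IsoformTemplate],
    config: ReadFilterConfig | None = None,
) -> pd.DataFrame:
    """Per-isoform support counts and full-length proportions.

    A read is full-length when it is at least ``min_length_full`` nt long and
    its spanned junctions cover every junction of the assigned template (the
    pie-chart semantics: proportions are taken over full-length reads only).
    """
    config = config or ReadFilterConfig()
    rows = {
        tid: {"isoform": tid, "junction_reads": 0, "full_length_reads": 0}
        for tid in templates
    }
    for a in assignments:
        if a.isoform_id is None:
            continue
        if a.isoform_id not in templates:
            raise KeyError(f"assignment references unknown template {a.isoform_id!r}")
        rows[a.isoform_id]["junction_reads"] += 1
        tpl = templates[a.isoform_id]
        if (
            a.read_length >= config.min_length_full
            and a.spanned_junctions >= tpl.junction_keys
        ):
            rows[a.isoform_id]["full_length_reads"] += 1
    df = pd.DataFrame(list(rows.values())).set_index("isoform")
    total_fl = df["full_length_reads"].sum()
    df["full_length_proportion"] = (
        df["full_length_reads"] / total_fl if total_fl > 0 else np.nan
    )
    return df


# ---------------------------------------------------------------------------
# Built-in substitution-tolerant placer
# ---------------------------------------------------------------------------

class AnchorMatcher:
    """Place reads on templates by exact k-mer anchors with offset voting.

    Reads simulated (or sequenced) with substitution-only errors map to a
    template at a single offset; anchors are exact k-mers sampled along the
    read, each voting for ``template_pos - read_pos``.  The aligned block is
    the template span covered by the winning offset's anchors.  The reported
    mapq is a confidence surrogate: 60 when at least ``min_anchors`` agree,
    else 0 (shared exons make cross-template placement expected; specificity
    is the resolver's job, not mapq's).
    """

    def __init__(
        self,
        templates: Mapping[str, IsoformTemplate] | Sequence[IsoformTemplate],
        k: int = 21,
        step: int = 5,
        min_anchors: int = 3,
    ) -> None:
        if not isinstance(templates, Mapping):
            templates = {t.id: t for t in templates}
        self.templates = dict(templates)
        self.k, self.step, self.min_anchors = k, step, min_anchors
        self._index: dict[str, dict[str, list[int]]] = {}
        for tid, tpl in self.templates.items():
            idx: dict[str, list[int]] = {}
            seq = tpl.sequence
            for i in range(len(seq) - k + 1):
                idx.setdefault(seq[i : i + k], []).append(i)
            self._index[tid] = idx

    def align(self, read: LongRead) -> list[AlignmentRecord]:
        k = self.k
        anchors = [
            (i, read.sequence[i : i + k])
            for i in range(0, max(1, len(read.sequence) - k + 1), self.step)
        ]
        records = []
        for tid, idx in self._index.items():
            votes: Counter[int] = Counter()
            for rpos, kmer in anchors:
                for tpos in idx.get(kmer, ()):
                    votes[tpos - rpos] += 1
            if not votes:
                continue
            offset, support = votes.most_common(1)[0]
            if support < self.min_anchors:
                continue
            spans = [
                (rpos + offset, rpos + offset + k)
                for rpos, kmer in anchors
                if offset in [t - rpos for t in idx.get(kmer, ())]
            ]
            block = (min(s for s, _ in spans), max(e for _, e in spans))
            records.append(
                AlignmentRecord(read.id, tid, 60, [block], len(read.sequence))
            )
        return records


def classify_reads(
    reads: Iterable[LongRead],
    templates: Mapping[str, IsoformTemplate] | Sequence[IsoformTemplate],
    matcher: AnchorMatcher | None = None,
    min_mapq: int = 20,
    min_overhang: int = 8,
) -> list[ReadAssignment]:
    """Align (built-in matcher) and resolve every read; unplaced reads get
    ``no_junction``."""
    if not isinstance(templates, Mapping):
        templates = {t.id: t for t in templates}
    matcher = matcher or AnchorMatcher(templates)
    out = []
    for read in reads:
        alns = matcher.align(read)
        if not alns:
            out.append(
                ReadAssignment(read.id, None, frozenset(), False, "no_junction",
                               len(read.sequence))
            )
        else:
            out.append(resolve_read(alns, templates, min_mapq, min_overhang))
    return out


# ---------------------------------------------------------------------------
# External alignment input (SAM / PAF)
# ---------------------------------------------------------------------------

def read_alignments_sam(path: str) -> list[AlignmentRecord]:
    """Load template-space alignments from SAM; blocks from the CIGAR."""
    import pysam

    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            blocks = _merge_adjacent(aln.get_blocks())
            records.append(
                AlignmentRecord(
                    aln.query_name,
                    aln.reference_name,
                    aln.mapping_quality,
                    blocks,
                    aln.query_length or (aln.infer_read_length() or 0),
                )
            )
    return records


def read_alignments_paf(path: str) -> list[AlignmentRecord]:
    """Load PAF alignments (single block per record; no CIGAR interpretation)."""
    records = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            records.append(
                AlignmentRecord(
                    read_id=f[0],
                    template_id=f[5],
                    mapq=int(f[11]),
                    blocks=[(int(f[7]), int(f[8]))],
                    read_length=int(f[1]),
                )
            )
    return records


def _merge_adjacent(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(b) for b in merged]


def assignments_to_frame(assignments: Iterable[ReadAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": a.read_id,
            "isoform": a.isoform_id,
            "reason": a.reason,
            "n_junctions_spanned": len(a.spanned_junctions),
            "read_length": a.read_length,
        }
        for a in assignments
    )


# ---------------------------------------------------------------------------
# FASTQ/FASTA input
# ---------------------------------------------------------------------------

def read_long_reads(path: str) -> list[LongRead]:
    from Bio import SeqIO

    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = rec.letter_annotations.get("phred_quality")
        reads.append(LongRead(rec.id, str(rec.seq).upper(), qual))
    return reads
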