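"""ORF prediction across fusion junctions and variant-consequence calling.

The two fusion isoforms skip the canonical first exon and therefore need
alternative start codons: an ATG near the 3' end of the SSR exon (whose
frame, read into the SINE cassette, hits an in-frame stop), and a second ATG
inside the SINE whose frame runs through the downstream ORF.  This module
predicts those ORFs, attributes each residue to the exon contributing its
codon's first nucleotide, compares N-termini against the reference protein,
and evaluates small deletions (frameshift / premature stop / knock-out
call) — the computational side of characterising an engineered 4-bp allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from .gene_model import ModelError, SplicedTranscript

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptAnnotation:
    """A spliced transcript plus candidate translation starts.

    ``boundaries``: exon id -> half-open span in 0-based transcript coords.
    ``candidate_starts``: (1-based position of the A of an ATG, provenance).
    """

    sequence: str
    exon_chain: list[str]
    boundaries: dict[str, tuple[int, int]]
    candidate_starts: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for pos, _prov in self.candidate_starts:
            if self.sequence[pos - 1 : pos + 2] != "ATG":
                raise ModelError(f"candidate start at {pos} is not on an ATG")

    @classmethod
    def from_spliced(
        cls, tx: SplicedTranscript, starts: Sequence[tuple[int, str]] = ()
    ) -> "TranscriptAnnotation":
        return cls(tx.sequence, list(tx.exon_chain), dict(tx.boundaries), list(starts))

    def exon_of(self, pos0: int) -> str:
        for eid in self.exon_chain:
            s, e = self.boundaries[eid]
            if s <= pos0 < e:
                return eid
        raise ModelError(f"position {pos0} outside transcript")


@dataclass
class OrfResult:
    start: int                 # 1-based transcript position of the ATG's A
    stop: int | None           # 1-based position of the stop codon's first base
    protein: str
    residue_exons: list[str]   # exon of origin per residue (codon's first nt)
    open_ended: bool = False   # ran off the sequence without a stop

    @property
    def aa_length(self) -> int:
        return len(self.protein)


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        try:
            return str(Seq(codon).translate())
        except Exception:
            return "X"
    return str(Seq(codon).translate())


def find_orfs(
    transcript: TranscriptAnnotation, policy: str = "annotated_starts"
) -> list[OrfResult]:
    """Translate from admitted starts until the first in-frame stop.

    Policies: ``annotated_starts`` (the transcript's curated ATGs),
    ``first_atg``, ``all_atgs``.  Standard nuclear code; codons containing N
    translate to X.  Returns one result per start, in start order.
    """
    seq = transcript.sequence
    if policy == "annotated_starts":
        starts = sorted(p for p, _ in transcript.candidate_starts)
    elif policy in ("first_atg", "all_atgs"):
        starts = [i + 1 for i in range(len(seq) - 2) if seq[i : i + 3] == "ATG"]
        if policy == "first_atg":
            starts = starts[:1]
    else:
        raise ValueError(f"unknown start policy {policy!r}")

    results = []
    for start in starts:
        protein, exons = [], []
        stop: int | None = None
        open_ended = True
        for i in range(start - 1, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                stop = i + 1
                open_ended = False
                break
            protein.append(_translate_codon(codon))
            exons.append(transcript.exon_of(i))
        results.append(OrfResult(start, stop, "".join(protein), exons, open_ended))
    return results


def residues_from_exon(orf: OrfResult, exon_id: str, transcript: TranscriptAnnotation) -> int:
    """Residues whose codon's first nucleotide lies in ``exon_id``.

    With the SSR ATG at 362 of a 448-nt exon this is (448-362+1)/3 = 29; with
    the SINE ATG at 48 of 65 it is (65-48+1)/3 = 6.
    """
    if exon_id not in transcript.boundaries:
        raise ModelError(f"exon {exon_id!r} absent from transcript boundary table")
    return sum(e == exon_id for e in orf.residue_exons)


@dataclass
class NTermComparison:
    novel: int      # prefix unique to the new protein
    replaced: int   # reference prefix absent from the new protein
    shared: int     # longest common C-terminal block


def compare_nterm(new_protein: str, reference_protein: str) -> NTermComparison:
    """Longest-common-suffix decomposition of two proteins.

    For the SINE isoform versus the reference this yields 6 novel residues
    replacing the 16 encoded by the canonical first exon.
    """
    if not new_protein or not reference_protein:
        raise ValueError("proteins must be non-empty")
    shared = 0
    while (
        shared < min(len(new_protein), len(reference_protein))
        and new_protein[-1 - shared] == reference_protein[-1 - shared]
    ):
        shared += 1
    return NTermComparison(
        novel=len(new_protein) - shared,
        replaced=len(reference_protein) - shared,
        shared=shared,
    )


def annotate_isoform(model, exon_chain: Sequence[str]) -> TranscriptAnnotation:
    """Splice an exon chain and lift the model's annotated ATGs into
    transcript coordinates."""
    from .gene_model import splice

    tx = splice(exon_chain, model)
    starts = []
    for eid in exon_chain:
        e = model.exon(eid)
        if e.annotated_start is not None:
            starts.append((tx.boundaries[eid][0] + e.annotated_start, "annotated"))
    return TranscriptAnnotation.from_spliced(tx, starts)


# ---------------------------------------------------------------------------
# Variant consequences
# ---------------------------------------------------------------------------

@dataclass
class VariantConsequence:
    frameshift: bool
    premature_stop: int | None   # 1-based (edited-transcript) stop-codon start
    truncated_length: int        # aa length of the post-edit ORF
    ko_call: bool
    intact_length: int


def apply_deletion(
    transcript: TranscriptAnnotation, del_start: int, del_end: int
) -> TranscriptAnnotation:
    """Excise a 1-based inclusive transcript interval; shift boundaries/starts."""
    n = len(transcript.sequence)
    if not (1 <= del_start <= del_end <= n):
        raise IndexError(f"deletion {del_start}-{del_end} outside transcript [1,{n}]")
    dlen = del_end - del_start + 1
    seq = transcript.sequence[: del_start - 1] + transcript.sequence[del_end:]

    def shift(pos0: int) -> int:
        # positions are half-open block edges in 0-based coords
        if pos0 <= del_start - 1:
            return pos0
        return max(del_start - 1, pos0 - dlen)

    boundaries = {
        eid: (shift(s), shift(e)) for eid, (s, e) in transcript.boundaries.items()
    }
    starts = []
    for pos, prov in transcript.candidate_starts:
        if del_start <= pos <= del_end:
            continue  # start itself deleted
        new_pos = pos if pos < del_start else pos - dlen
        if seq[new_pos - 1 : new_pos + 2] == "ATG":
            starts.append((new_pos, prov))
    out = TranscriptAnnotation(seq, list(transcript.exon_chain), boundaries, starts)
    return out


def consequence(
    orf_before: OrfResult,
    transcript_after: TranscriptAnnotation,
    deletion: tuple[int, int],
    ko_fraction: float = 0.2,
) -> VariantConsequence:
    """Re-run translation from the original start after an excision.

    Frameshift iff the deletion length is not a multiple of 3 and the
    deletion lies at/after the start codon (inside the CDS).  The knock-out
    call is a declared heuristic: frameshift plus truncation below
    ``ko_fraction`` of the intact ORF length.
    """
    del_start, del_end = deletion
    dlen = del_end - del_start + 1
    start = orf_before.start
    frameshift = (dlen % 3 != 0) and del_start >= start
    # start position in edited coordinates
    new_start = start if del_start > start else start - min(dlen, start - del_start + 1)
    candidates = [p for p, _ in transcript_after.candidate_starts if p == new_start]
    if not candidates:
        # translation aborted at the source: no ATG at the original start
        return VariantConsequence(
            frameshift=frameshift,
            premature_stop=None,
            truncated_length=0,
            ko_call=True,
            intact_length=orf_before.aa_length,
        )
    probe = TranscriptAnnotation(
        transcript_after.sequence,
        transcript_after.exon_chain,
        transcript_after.boundaries,
        [(new_start, "annotated")],
    )
    new_orf = find_orfs(probe, "annotated_starts")[0]
    truncated = new_orf.aa_length
    premature = new_orf.stop if truncated < orf_before.aa_length else None
    ko = frameshift and truncated < ko_fraction * orf_before.aa_length
    return VariantConsequence(
        frameshift=frameshift,
        premature_stop=premature,
        truncated_length=truncated,
        ko_call=ko,
        intact_length=orf_before.aa_length,
    )
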