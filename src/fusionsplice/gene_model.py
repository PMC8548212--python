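"""Coordinate-safe locus representation and spliced-sequence construction.

The locus of interest is a single gene whose transcription can start either
from the canonical first exon (E1) or from a repeat-derived exon (an SSR)
hundreds of kilobases upstream, optionally routing through a SINE-derived
cassette exon before joining the common coding exons.  Everything downstream
(template enumeration, read classification, ORF prediction) is built on the
primitives here.

Conventions
-----------
* External coordinates (files, reports, printed positions) are 1-based
  inclusive, matching the ``chr5:51,912,715-51,912,718`` style used for the
  engineered deletion allele.
* Internal arithmetic is 0-based half-open; :class:`GenomicInterval` carries
  the converters so the off-by-one risk lives in exactly one place.
* Exon sequences are stored genome-forward; :func:`splice` applies the
  reverse complement once, at assembly, for minus-strand models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class IntervalError(ValueError):
    """Raised for malformed genomic intervals (start > end, bad strand...)."""


class ModelError(ValueError):
    """Raised for inconsistent gene models or unknown exon references."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise IntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start > end)"
            )
        if self.start < 1:
            raise IntervalError("1-based coordinates must be >= 1")
        if self.strand not in ("+", "-"):
            raise IntervalError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    # -- converters ---------------------------------------------------------
    def to_zero_based(self) -> tuple[int, int]:
        """Return the equivalent 0-based half-open (start, end)."""
        return self.start - 1, self.end

    @classmethod
    def from_zero_based(
        cls, chrom: str, start0: int, end0: int, strand: str = "+"
    ) -> "GenomicInterval":
        return cls(chrom, start0 + 1, end0, strand)


def interval_length(interval: GenomicInterval) -> int:
    """Nucleotide count of a 1-based inclusive interval (end - start + 1)."""
    return interval.length


@dataclass(frozen=True)
class Exon:
    """One exon of the locus.

    ``annotated_start`` / ``annotated_stop`` are optional 1-based positions
    *within the exon* (transcript orientation) marking a putative ATG or an
    in-frame stop codon; they must leave room for a full codon.
    """

    id: str
    interval: GenomicInterval
    role: str = "internal"  # novel_start | reference_first | internal | terminal
    annotated_start: int | None = None
    annotated_stop: int | None = None

    _ROLES = ("novel_start", "reference_first", "internal", "terminal")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ModelError(f"unknown exon role {self.role!r}")
        for pos in (self.annotated_start, self.annotated_stop):
            if pos is not None and not (1 <= pos <= self.length - 2):
                raise ModelError(
                    f"annotated position {pos} outside [1, {self.length - 2}] "
                    f"for exon {self.id}"
                )

    @property
    def length(self) -> int:
        return self.interval.length


SequenceAccessor = Callable[[GenomicInterval], str]


@dataclass
class GeneModel:
    """A single locus: ordered exons plus a genome sequence accessor.

    Exons are listed in transcription order (increasing coordinates on '+',
    decreasing on '-') and must not overlap.  The accessor returns the
    genome-forward sequence of any interval.
    """

    chrom: str
    strand: str
    exons: list[Exon]
    sequence: SequenceAccessor

    def __post_init__(self) -> None:
        ids = [e.id for e in self.exons]
        if len(set(ids)) != len(ids):
            raise ModelError("exon ids must be unique within a model")
        sign = 1 if self.strand == "+" else -1
        for a, b in zip(self.exons, self.exons[1:]):
            if sign * (b.interval.start - a.interval.end) <= 0 and sign > 0:
                raise ModelError(f"exons {a.id},{b.id} overlap or are out of order")
            if sign < 0 and (a.interval.start - b.interval.end) <= 0:
                raise ModelError(f"exons {a.id},{b.id} overlap or are out of order")

    # -- lookups ------------------------------------------------------------
    @property
    def exon_ids(self) -> list[str]:
        return [e.id for e in self.exons]

    def exon(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.id == exon_id:
                return e
        raise ModelError(f"unknown exon id {exon_id!r}")

    def exon_index(self, exon_id: str) -> int:
        for i, e in enumerate(self.exons):
            if e.id == exon_id:
                return i
        raise ModelError(f"unknown exon id {exon_id!r}")

    def exon_sequence(self, exon_id: str) -> str:
        """Transcript-orientation sequence of one exon."""
        e = self.exon(exon_id)
        seq = self.sequence(e.interval).upper()
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class SplicedTranscript:
    """Result of splicing an exon chain: sequence plus the boundary table.

    ``boundaries`` maps each exon id to its half-open span in 0-based
    transcript coordinates; ``junction_breakpoints`` are the 0-based offsets
    of each acceptor exon's first base (equivalently the cumulative length of
    the upstream exons).
    """

    exon_chain: list[str]
    sequence: str
    boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def junction_breakpoints(self) -> list[int]:
        return [self.boundaries[e][0] for e in self.exon_chain[1:]]

    def exon_of_position(self, pos0: int) -> str:
        for eid in self.exon_chain:
            s, e = self.boundaries[eid]
            if s <= pos0 < e:
                return eid
        raise ModelError(f"transcript position {pos0} outside [0, {len(self.sequence)})")

    def to_genomic(self, pos0: int, model: GeneModel) -> int:
        """Map a 0-based transcript position back to a 1-based genomic one."""
        eid = self.exon_of_position(pos0)
        s, _ = self.boundaries[eid]
        offset = pos0 - s
        iv = model.exon(eid).interval
        if model.strand == "+":
            return iv.start + offset
        return iv.end - offset


def splice(exon_ids: Sequence[str], model: GeneModel) -> SplicedTranscript:
    """Concatenate exon sequences in transcription order.

    Raises :class:`ModelError` if ids are unknown or not given in the model's
    transcription order.
    """
    if not exon_ids:
        raise ModelError("cannot splice an empty exon chain")
    idx = [model.exon_index(e) for e in exon_ids]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ModelError(f"exon chain {list(exon_ids)} not in transcription order")
    parts: list[str] = []
    boundaries: dict[str, tuple[int, int]] = {}
    pos = 0
    for eid in exon_ids:
        seq = model.exon_sequence(eid)
        boundaries[eid] = (pos, pos + len(seq))
        pos += len(seq)
        parts.append(seq)
    return SplicedTranscript(list(exon_ids), "".join(parts), boundaries)


# ---------------------------------------------------------------------------
# Transcription-time estimate
# ---------------------------------------------------------------------------

def transcription_time(length_kb: float, rate_kb_per_min: float) -> float:
    """Hours needed to transcribe ``length_kb`` at ``rate_kb_per_min``.

    A ~600 kb pre-mRNA takes 10 h at 1 kb/min and ~3.3 h at 3 kb/min.
    """
    if rate_kb_per_min <= 0:
        raise ValueError("elongation rate must be > 0 kb/min")
    if length_kb < 0:
        raise ValueError("transcript length must be >= 0")
    return length_kb / rate_kb_per_min / 60.0


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding (half away from zero), e.g. 3.3333 -> 3.3, 0.25 -> 0.3."""
    import decimal

    q = decimal.Decimal(10) ** -decimals
    d = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


# ---------------------------------------------------------------------------
# IO: GFF3 + FASTA + config
# ---------------------------------------------------------------------------

def fasta_accessor(fasta_path: str) -> SequenceAccessor:
    """Sequence accessor backed by an indexed FASTA (pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    def get(iv: GenomicInterval) -> str:
        s0, e0 = iv.to_zero_based()
        return str(fa[iv.chrom][s0:e0])

    return get


def read_gene_model(
    gff3_path: str,
    fasta_path: str,
    exon_config: Mapping[str, Mapping] | None = None,
) -> GeneModel:
    """Load a single-locus gene model from GFF3 exon features + genome FASTA.

    ``exon_config`` optionally overrides per-exon ``role`` /
    ``annotated_start`` / ``annotated_stop`` (keyed by exon ID), mirroring the
    JSON/YAML block the generator writes.
    """
    import pandas as pd

    rows = []
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "exon":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                dict(
                    chrom=f[0],
                    start=int(f[3]),
                    end=int(f[4]),
                    strand=f[6],
                    id=attrs.get("ID", f"exon{len(rows)}"),
                    role=attrs.get("role", "internal"),
                    annotated_start=attrs.get("annotated_start"),
                    annotated_stop=attrs.get("annotated_stop"),
                )
            )
    if not rows:
        raise ModelError(f"no exon features found in {gff3_path}")
    df = pd.DataFrame(rows)
    strand = df["strand"].iloc[0]
    chrom = df["chrom"].iloc[0]
    df = df.sort_values("start", ascending=(strand == "+")).reset_index(drop=True)

    cfg = dict(exon_config or {})
    exons = []
    for r in df.itertuples():
        over = cfg.get(r.id, {})
        ann_start = over.get("annotated_start", r.annotated_start)
        ann_stop = over.get("annotated_stop", r.annotated_stop)
        exons.append(
            Exon(
                id=r.id,
                interval=GenomicInterval(chrom, r.start, r.end, strand),
                role=over.get("role", r.role),
                annotated_start=None if ann_start is None else int(ann_start),
                annotated_stop=None if ann_stop is None else int(ann_stop),
            )
        )
    return GeneModel(chrom, strand, exons, fasta_accessor(fasta_path))


def write_gff3(model_rows: Iterable[Mapping], path: str) -> None:
    """Write exon rows (chrom/start/end/strand/id/role/annotated_*) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in model_rows:
            attrs = [f"ID={r['id']}", f"role={r.get('role', 'internal')}"]
            if r.get("annotated_start") is not None:
                attrs.append(f"annotated_start={r['annotated_start']}")
            if r.get("annotated_stop") is not None:
                attrs.append(f"annotated_stop={r['annotated_stop']}")
            fh.write(
                "\t".join(
                    [
                        str(r["chrom"]),
                        "fusionsplice",
                        "exon",
                        str(r["start"]),
                        str(r["end"]),
                        ".",
                        r.get("strand", "+"),
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
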