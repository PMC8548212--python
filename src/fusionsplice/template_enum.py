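"""Enumeration of candidate isoform templates.

Long reads are classified by aligning them to artificial reference sequences
("templates"), one per candidate exon chain.  Two enumeration modes are
provided:

``chains``
    every order-preserving exon subsequence that begins at an allowed start
    exon and ends at the required terminal exon (optional internal exons are
    free, required ones are forced, excluded ones are dropped);

``junction_pairs``
    one minimal two-exon template per ordered exon pair, useful when only a
    single junction needs to be interrogated.

The combination rule behind any particular published template count is a
configuration, not a constant: the enumerators are exact and deterministic,
and the count follows from the constraints you pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .gene_model import GeneModel, ModelError


class ConstraintError(ValueError):
    """Raised when enumeration constraints are empty or reference unknown exons."""


@dataclass(frozen=True)
class Junction:
    """A donor->acceptor splice in transcript coordinates.

    ``breakpoint`` is the 0-based transcript offset of the acceptor's first
    base, i.e. the cumulative length of the upstream exons in the chain.
    """

    donor: str
    acceptor: str
    breakpoint: int

    @property
    def breakpoint_1based(self) -> int:
        return self.breakpoint + 1


@dataclass
class IsoformTemplate:
    id: str
    exon_chain: list[str]
    junctions: list[Junction]
    sequence: str

    def __post_init__(self) -> None:
        bps = [j.breakpoint for j in self.junctions]
        if bps != sorted(set(bps)):
            raise ModelError(f"template {self.id}: breakpoints must strictly increase")
        if len(self.junctions) != len(self.exon_chain) - 1:
            raise ModelError(
                f"template {self.id}: junction count must be |chain| - 1"
            )

    @property
    def junction_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset((j.donor, j.acceptor) for j in self.junctions)


def template_from_chain(chain: Sequence[str], model: GeneModel) -> IsoformTemplate:
    """Build one template (spliced sequence + junction table) from an exon chain."""
    from .gene_model import splice

    tx = splice(chain, model)
    junctions = [
        Junction(d, a, tx.boundaries[a][0])
        for d, a in zip(chain, chain[1:])
    ]
    return IsoformTemplate("-".join(chain), list(chain), junctions, tx.sequence)


def enumerate_templates(
    model: GeneModel,
    mode: str = "chains",
    start_exons: Sequence[str] | None = None,
    terminal_exon: str | None = None,
    required_exons: Sequence[str] = (),
    excluded_exons: Sequence[str] = (),
    max_chain_length: int | None = None,
    allowed_pairs: Iterable[tuple[str, str]] | None = None,
) -> list[IsoformTemplate]:
    """Enumerate candidate isoform templates, lexicographically sorted by id.

    In ``chains`` mode the count for s start exons and k free internal exons
    is s * 2**k (before the ``max_chain_length`` cap).
    """
    known = set(model.exon_ids)
    for name, ids in (
        ("start", start_exons or ()),
        ("terminal", [terminal_exon] if terminal_exon else ()),
        ("required", required_exons),
        ("excluded", excluded_exons),
    ):
        bad = set(ids) - known
        if bad:
            raise ConstraintError(f"unknown {name} exon ids: {sorted(bad)}")

    if mode == "chains":
        if not start_exons:
            raise ConstraintError("chains mode needs at least one allowed start exon")
        if terminal_exon is None:
            raise ConstraintError("chains mode needs a required terminal exon")
        order = model.exon_ids
        t_idx = model.exon_index(terminal_exon)
        required = set(required_exons)
        excluded = set(excluded_exons)
        chains: list[list[str]] = []
        for start in start_exons:
            s_idx = model.exon_index(start)
            if s_idx >= t_idx or start in excluded:
                continue
            between = [
                e
                for e in order[s_idx + 1 : t_idx]
                if e not in excluded
            ]
            forced = [e for e in between if e in required]
            free = [e for e in between if e not in required]
            for r in range(len(free) + 1):
                for combo in itertools.combinations(free, r):
                    members = set(forced) | set(combo)
                    chain = [start] + [e for e in between if e in members] + [terminal_exon]
                    if max_chain_length is not None and len(chain) > max_chain_length:
                        continue
                    chains.append(chain)
        templates = [template_from_chain(c, model) for c in chains]

    elif mode == "junction_pairs":
        order = model.exon_ids
        excluded = set(excluded_exons)
        if allowed_pairs is not None:
            pairs = list(allowed_pairs)
        else:
            pairs = [
                (a, b)
                for i, a in enumerate(order)
                for b in order[i + 1 :]
                if a not in excluded and b not in excluded
            ]
        for a, b in pairs:
            if model.exon_index(a) >= model.exon_index(b):
                raise ConstraintError(f"pair ({a},{b}) not in transcription order")
        templates = [template_from_chain([a, b], model) for a, b in pairs]
    else:
        raise ConstraintError(f"unknown enumeration mode {mode!r}")

    templates.sort(key=lambda t: t.id)
    return templates


# ---------------------------------------------------------------------------
# Serialisation: template FASTA + companion junction TSV
# ---------------------------------------------------------------------------

def write_templates(
    templates: Sequence[IsoformTemplate],
    fasta_path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    """Write templates as FASTA (chain/junctions as id-line tags) plus a TSV.

    The TSV carries one row per junction: template id, junction index, donor,
    acceptor and the 1-based transcript coordinate of the acceptor's first
    base.  Refuses duplicate template ids and empty sets.
    """
    if not templates:
        raise ValueError("refusing to write an empty template set")
    ids = [t.id for t in templates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate template ids; write refused")

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for t in templates:
        desc = "chain={} junctions={}".format(
            ",".join(t.exon_chain),
            ",".join(str(j.breakpoint_1based) for j in t.junctions) or ".",
        )
        records.append(SeqRecord(Seq(t.sequence), id=t.id, description=desc))
    seqio_write(records, str(fasta_path), "fasta")

    if tsv_path is None:
        tsv_path = str(fasta_path) + ".junctions.tsv"
    with open(tsv_path, "w") as fh:
        fh.write("template_id\tjunction_index\tdonor\tacceptor\tbreakpoint_1based\n")
        for t in templates:
            for i, j in enumerate(t.junctions):
                fh.write(f"{t.id}\t{i}\t{j.donor}\t{j.acceptor}\t{j.breakpoint_1based}\n")


def read_templates(
    fasta_path: str | Path, tsv_path: str | Path | None = None
) -> list[IsoformTemplate]:
    """Round-trip reader for :func:`write_templates` output."""
    from Bio import SeqIO

    if tsv_path is None:
        tsv_path = str(fasta_path) + ".junctions.tsv"
    junctions: dict[str, list[Junction]] = {}
    with open(tsv_path) as fh:
        header = fh.readline()
        assert header.startswith("template_id")
        for line in fh:
            tid, _idx, donor, acceptor, bp1 = line.rstrip("\n").split("\t")
            junctions.setdefault(tid, []).append(
                Junction(donor, acceptor, int(bp1) - 1)
            )
    templates = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tags = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        chain = tags["chain"].split(",")
        templates.append(
            IsoformTemplate(rec.id, chain, junctions.get(rec.id, []), str(rec.seq))
        )
    return templates
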