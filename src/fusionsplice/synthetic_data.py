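"""Synthetic fixtures with planted ground truth for the whole pipeline.

Everything the analyses consume can be generated here from a seed: a
mini-locus genome whose exon geometry reproduces the printed positions of
the real one (a 448-nt SSR first exon with a putative ATG at 362-364; a
65-nt SINE cassette carrying, relative to the upstream reading frame, a TGA
at 19-21 and its own ATG at 48-50; a canonical first exon contributing 16
residues; shared downstream coding exons), long reads drawn from a known
isoform mixture, spliced short reads at planted junction depths, a 2x2x2
factorial expression matrix with planted differential clusters, and promoter
sets with planted motif prevalence.

Inter-exon distances are scaled down (5-kb spacers standing in for the real
566.7-kb and 200-kb gaps) so the fixture genome stays desk-sized; the real
pre-mRNA length enters the transcription-time estimate as an explicit
argument, never from this model.  The SINE's six encoded residues are set to
MDEGYF.  Every generator is a pure function of (spec, seed): same inputs,
identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_model import (
    Exon,
    GeneModel,
    GenomicInterval,
    write_gff3,
)
from .junction_quant import SplicedRead
from .long_read_classifier import LongRead
from .motif_enrichment import PWM
from .template_enum import IsoformTemplate, template_from_chain

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


class ConstructionError(ValueError):
    """Raised when a fixture cannot satisfy its planted-codon geometry."""


# ---------------------------------------------------------------------------
# Fixture specification
# ---------------------------------------------------------------------------

def _default_exon_lengths() -> dict[str, int]:
    lengths = {"SSR": 448, "SINE": 65, "E1": 100}
    lengths.update({f"E{i}": 160 for i in range(2, 13)})
    lengths["E13"] = 400
    return lengths


@dataclass
class LocusSpec:
    exon_lengths: dict[str, int] = field(default_factory=_default_exon_lengths)
    ssr_atg: int = 362        # 1-based within SSR
    sine_stop: int = 19       # TGA, upstream frame
    sine_first_atg: int = 10  # decoy ATG upstream of the initiating one
    sine_atg: int = 48
    e1_atg: int = 53          # leaves a 48-nt CDS suffix: 16 residues
    stop_offset_in_e13: int = 100  # plant the shared ORF stop past this offset
    spacer: int = 5000
    flank: int = 1000
    chrom: str = "chrL"
    strand: str = "+"


@dataclass
class LongReadSpec:
    n_reads: int = 500
    mixture: dict[str, float] = field(
        default_factory=lambda: {"SSR-SINE-E2": 0.6, "SSR-E2": 0.25, "ref": 0.15}
    )
    error_rate: float = 0.02
    p_full_length: float = 0.6
    min_fragment: int = 500
    head_noise: int = 50      # synthetic primer/head bases, removed by QC trim


@dataclass
class JunctionReadSpec:
    # planted junction-spanning depths per sample: neurons mostly SINE-E2,
    # astrocytes all reference, progenitors mixed
    depths: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "neuron": {"SSR-E2": 8, "SINE-E2": 60, "E1-E2": 2},
            "astrocyte": {"SSR-E2": 0, "SINE-E2": 0, "E1-E2": 50},
            "opc": {"SSR-E2": 20, "SINE-E2": 22, "E1-E2": 18},
        }
    )
    gene_fpkm: dict[str, float] = field(
        default_factory=lambda: {"neuron": 5.0, "astrocyte": 4.0, "opc": 2.0}
    )
    n_nonspanning: int = 30
    read_half: int = 40       # bases on each side available for overhangs
    min_overhang: int = 8


def _default_patterns() -> dict[str, dict[str, float]]:
    # four shape-distinct KO-vs-WT patterns over (sex, organ), echoing the
    # observed ones: up in female cerebellum, up in both cerebella, down in
    # male cerebellum, down in both cerebella
    return {
        "I": {"F-KO-Cb": 1.2},
        "II": {"F-KO-Cb": 0.8, "M-KO-Cb": 0.8},
        "III": {"M-KO-Cb": -1.2},
        "IV": {"F-KO-Cb": -0.8, "M-KO-Cb": -0.8},
    }


@dataclass
class ExpressionSpec:
    replicates: int = 2
    n_null: int = 1800
    probes_per_cluster: int = 50
    sigma: float = 0.25
    baseline_range: tuple[float, float] = (6.0, 10.0)
    patterns: dict[str, dict[str, float]] = field(default_factory=_default_patterns)


@dataclass
class PromoterSpec:
    set_sizes: dict[str, int] = field(default_factory=lambda: {"setA": 200, "setB": 200})
    prevalence: dict[str, float] = field(default_factory=lambda: {"setA": 0.6, "setB": 0.2})
    flank: int = 1000
    gene_spacing: int = 5000
    motif: str = "ERE"
    chrom: str = "chrP"


# ---------------------------------------------------------------------------
# Sequence-engineering helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, n)])


def _scrub_atg(seq: list[str], lo0: int, hi0: int, keep_starts: set[int]) -> None:
    """Remove ATG windows starting in [lo0, hi0] (0-based) except keepers.

    Replacing the T with C can create neither a new ATG nor a stop codon, so
    a single pass suffices.
    """
    for s in range(lo0, min(hi0 + 1, len(seq) - 2)):
        if s in keep_starts:
            continue
        if seq[s] == "A" and seq[s + 1] == "T" and seq[s + 2] == "G":
            seq[s + 1] = "C"


def _scrub_stops(
    seq: list[str], codon_starts: Sequence[int], rng: np.random.Generator,
    keep_starts: set[int] = frozenset(),
) -> None:
    """Replace stop codons at the given 0-based starts with C/A-only codons
    (which can never spawn a stop or an ATG in any frame)."""
    safe = ["CAC", "CCA", "ACC", "CAA"]
    for s in codon_starts:
        if s in keep_starts:
            continue
        if "".join(seq[s : s + 3]) in _STOPS:
            seq[s : s + 3] = list(safe[rng.integers(0, len(safe))])


def _plant(seq: list[str], pos0: int, codon: str) -> None:
    seq[pos0 : pos0 + len(codon)] = list(codon)


def _scrub_atg_protected(
    seq: list[str], lo0: int, hi0: int, keep_starts: set[int], protected: set[int]
) -> None:
    """Post-plant ATG cleanup that never touches planted positions.

    Mutates the first unprotected base of each stray ATG to C (which cannot
    spawn a stop or another ATG in any frame).
    """
    for s in range(lo0, min(hi0 + 1, len(seq) - 2)):
        if s in keep_starts:
            continue
        if seq[s] == "A" and seq[s + 1] == "T" and seq[s + 2] == "G":
            for p in (s + 1, s, s + 2):
                if p not in protected:
                    seq[p] = "C"
                    break
            else:
                raise ConstructionError(
                    f"cannot scrub ATG at {s}: all bases planted"
                )


# ---------------------------------------------------------------------------
# Locus fixture
# ---------------------------------------------------------------------------

@dataclass
class LocusFixture:
    spec: LocusSpec
    genome: str
    model: GeneModel
    exon_rows: list[dict]
    truth: dict

    ISOFORM_CHAINS = {
        "ref": ["E1"] + [f"E{i}" for i in range(2, 14)],
        "SSR-E2": ["SSR"] + [f"E{i}" for i in range(2, 14)],
        "SSR-SINE-E2": ["SSR", "SINE"] + [f"E{i}" for i in range(2, 14)],
    }

    def isoform_templates(self) -> dict[str, IsoformTemplate]:
        out = {}
        for name, chain in self.ISOFORM_CHAINS.items():
            t = template_from_chain(chain, self.model)
            t.id = name
            out[name] = t
        return out

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fa = outdir / "genome.fa"
        with open(fa, "w") as fh:
            fh.write(f">{self.spec.chrom}\n")
            for i in range(0, len(self.genome), 80):
                fh.write(self.genome[i : i + 80] + "\n")
        gff = outdir / "model.gff3"
        write_gff3(self.exon_rows, str(gff))
        truth = outdir / "truth.json"
        truth.write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return {"genome": str(fa), "gff3": str(gff), "truth": str(truth)}


def build_fixture_genome(spec: LocusSpec | None = None, seed: int = 0) -> LocusFixture:
    """Engineer the mini-locus and verify every planted codon on re-read."""
    spec = spec or LocusSpec()
    rng = np.random.default_rng(seed)
    L = spec.exon_lengths

    exon_seqs: dict[str, list[str]] = {e: _random_seq(rng, n) for e, n in L.items()}

    # SSR: no ATG before the annotated one; its frame clean to the exon end
    ssr = exon_seqs["SSR"]
    a0 = spec.ssr_atg - 1
    _scrub_atg(ssr, 0, a0 - 1, keep_starts=set())
    _plant(ssr, a0, "ATG")
    _scrub_stops(ssr, range(a0, L["SSR"] - 2, 3), rng, keep_starts={a0})
    _plant(ssr, L["SSR"] - 3, "GAT")  # last SSR residue (D): distinct N-termini

    # SINE: upstream-frame stop at 19-21, decoy ATG at 10-12, MDEGYF from 48
    sine = exon_seqs["SINE"]
    s0, d0, g0 = spec.sine_stop - 1, spec.sine_first_atg - 1, spec.sine_atg - 1
    _scrub_atg(sine, 0, g0 - 1, keep_starts={d0})
    _scrub_stops(sine, range(0, s0, 3), rng)          # upstream frame, pre-stop
    _plant(sine, d0, "ATG")
    _plant(sine, s0, "TGA")
    _plant(sine, g0, "ATGGATGAAGGTTATTTT")            # M D E G Y F
    protected = set(range(d0, d0 + 3)) | set(range(s0, s0 + 3)) | set(range(g0, 65))
    _scrub_atg_protected(sine, 0, g0 - 1, keep_starts={d0}, protected=protected)

    # E1: canonical ATG leaves a 48-nt CDS suffix (16 residues)
    e1 = exon_seqs["E1"]
    m0 = spec.e1_atg - 1
    _scrub_atg(e1, 0, m0 - 1, keep_starts=set())
    _plant(e1, m0, "ATG")
    _scrub_stops(e1, range(m0, L["E1"] - 2, 3), rng, keep_starts={m0})
    _plant(e1, L["E1"] - 3, "GAA")  # last E1 residue (E)

    # shared downstream frame: clean until a planted TAA inside E13
    down_ids = [f"E{i}" for i in range(2, 14)]
    down = [b for e in down_ids for b in exon_seqs[e]]
    e13_off = sum(L[e] for e in down_ids[:-1])
    stop0 = next(
        p for p in range(0, len(down) - 2, 3) if p >= e13_off + spec.stop_offset_in_e13
    )
    _scrub_stops(down, range(0, stop0, 3), rng)
    _plant(down, stop0, "TAA")
    pos = 0
    for e in down_ids:
        exon_seqs[e] = down[pos : pos + L[e]]
        pos += L[e]

    # assemble the chromosome: flank + exons separated by spacers + flank
    order = ["SSR", "SINE", "E1"] + down_ids
    parts, exon_rows = [], []
    parts.append("".join(_random_seq(rng, spec.flank)))
    cursor = spec.flank
    ann = {
        "SSR": dict(role="novel_start", annotated_start=spec.ssr_atg),
        "SINE": dict(role="internal", annotated_start=spec.sine_atg,
                     annotated_stop=spec.sine_stop),
        "E1": dict(role="reference_first", annotated_start=spec.e1_atg),
        "E13": dict(role="terminal"),
    }
    for i, e in enumerate(order):
        if i:
            parts.append("".join(_random_seq(rng, spec.spacer)))
            cursor += spec.spacer
        seq = "".join(exon_seqs[e])
        start = cursor + 1  # 1-based
        exon_rows.append(
            dict(
                chrom=spec.chrom,
                start=start,
                end=cursor + len(seq),
                strand=spec.strand,
                id=e,
                **ann.get(e, dict(role="internal")),
            )
        )
        parts.append(seq)
        cursor += len(seq)
    parts.append("".join(_random_seq(rng, spec.flank)))
    genome = "".join(parts)

    def accessor(iv: GenomicInterval) -> str:
        s0_, e0_ = iv.to_zero_based()
        return genome[s0_:e0_]

    exons = [
        Exon(
            r["id"],
            GenomicInterval(spec.chrom, r["start"], r["end"], spec.strand),
            r["role"],
            r.get("annotated_start"),
            r.get("annotated_stop"),
        )
        for r in exon_rows
    ]
    model = GeneModel(spec.chrom, spec.strand, exons, accessor)
    truth = {
        "seed": seed,
        "exon_lengths": L,
        "ssr_atg": spec.ssr_atg,
        "sine_stop": spec.sine_stop,
        "sine_atg": spec.sine_atg,
        "e1_atg": spec.e1_atg,
        "shared_orf_stop_offset0_downstream": stop0,
        "spacer_stand_in_bp": spec.spacer,
        "real_gaps_kb": {"SSR_to_SINE": 200.0, "SSR_to_E2": 566.7},
        "genome_length": len(genome),
    }
    fixture = LocusFixture(spec, genome, model, exon_rows, truth)
    verify_fixture(fixture)
    return fixture


def verify_fixture(fix: LocusFixture) -> None:
    """Re-extract every planted codon from the assembled genome."""
    m, spec = fix.model, fix.spec

    def codon(exon: str, pos1: int) -> str:
        return m.exon_sequence(exon)[pos1 - 1 : pos1 + 2]

    checks = [
        (codon("SSR", spec.ssr_atg) == "ATG", "SSR ATG"),
        (codon("SINE", spec.sine_stop) == "TGA", "SINE upstream-frame TGA"),
        (codon("SINE", spec.sine_atg) == "ATG", "SINE ATG"),
        (codon("E1", spec.e1_atg) == "ATG", "E1 ATG"),
        ("ATG" not in m.exon_sequence("SSR")[: spec.ssr_atg - 1], "SSR pre-ATG clean"),
        (m.exon_sequence("SINE")[: spec.sine_atg - 1].count("ATG") == 1,
         "exactly one decoy ATG upstream in SINE"),
    ]
    # upstream frame clean before the SINE stop
    sine = m.exon_sequence("SINE")
    for p in range(0, spec.sine_stop - 1, 3):
        checks.append((sine[p : p + 3] not in _STOPS, f"SINE upstream frame codon {p}"))
    for ok, what in checks:
        if not ok:
            raise ConstructionError(f"fixture violates planted geometry: {what}")


# ---------------------------------------------------------------------------
# Long reads
# ---------------------------------------------------------------------------

def simulate_long_reads(
    fixture: LocusFixture, spec: LongReadSpec | None = None, seed: int = 0
) -> tuple[list[LongRead], pd.DataFrame]:
    """Draw reads from the isoform mixture with substitution errors.

    Each read gets ``head_noise`` random lead-in bases (removed by the QC
    head trim) and a flat quality string derived from the error rate.
    Returns the reads plus a per-read truth table (isoform, span).
    """
    spec = spec or LongReadSpec()
    if abs(sum(spec.mixture.values()) - 1.0) > 1e-9:
        raise ValueError("isoform mixture must sum to 1")
    if not spec.mixture:
        raise ValueError("empty isoform mixture")
    rng = np.random.default_rng(seed)
    templates = fixture.isoform_templates()
    names = sorted(spec.mixture)
    probs = np.array([spec.mixture[n] for n in names])
    q = 30 if spec.error_rate <= 0 else int(round(-10 * np.log10(spec.error_rate)))

    reads, rows = [], []
    for i in range(spec.n_reads):
        iso = names[rng.choice(len(names), p=probs)]
        tseq = templates[iso].sequence
        if rng.random() < spec.p_full_length or len(tseq) <= spec.min_fragment:
            start, length = 0, len(tseq)
        else:
            length = int(rng.integers(spec.min_fragment, len(tseq) + 1))
            start = int(rng.integers(0, len(tseq) - length + 1))
        frag = list(tseq[start : start + length])
        nerr = rng.binomial(length, spec.error_rate)
        for p in rng.choice(length, size=nerr, replace=False):
            frag[p] = str(rng.choice([b for b in "ACGT" if b != frag[p]]))
        head = "".join(_random_seq(rng, spec.head_noise))
        seq = head + "".join(frag)
        rid = f"read{i:05d}"
        reads.append(LongRead(rid, seq, [q] * len(seq)))
        rows.append(
            {"read_id": rid, "isoform": iso, "start": start, "length": length,
             "n_errors": int(nerr)}
        )
    return reads, pd.DataFrame(rows)


def write_fastq(reads: Sequence[LongRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in (r.quality or [30] * len(r.sequence)))
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Short junction reads
# ---------------------------------------------------------------------------

def simulate_junction_reads(
    fixture: LocusFixture, spec: JunctionReadSpec | None = None, seed: int = 0
) -> tuple[dict[str, list[SplicedRead]], dict]:
    """Planted junction-spanning (and decoy non-spanning) spliced alignments.

    Junction names use the diagnostic donor-acceptor labels (SSR-E2, SINE-E2,
    E1-E2).  Returns per-sample reads plus the planted truth (depths, FPKM).
    """
    spec = spec or JunctionReadSpec()
    rng = np.random.default_rng(seed)
    m = fixture.model
    edges = {}
    for name in ("SSR-E2", "SINE-E2", "E1-E2"):
        donor, acceptor = name.split("-")
        d, a = m.exon(donor).interval, m.exon(acceptor).interval
        edges[name] = (d.end, a.start)  # 1-based donor end / acceptor start

    out: dict[str, list[SplicedRead]] = {}
    for sample, depths in spec.depths.items():
        reads = []
        n = 0
        for jname, depth in depths.items():
            donor_end, acceptor_start = edges[jname]
            for _ in range(depth):
                o1 = int(rng.integers(spec.min_overhang, spec.read_half + 1))
                o2 = int(rng.integers(spec.min_overhang, spec.read_half + 1))
                blocks = [
                    (donor_end - o1, donor_end),
                    (acceptor_start - 1, acceptor_start - 1 + o2),
                ]
                reads.append(SplicedRead(f"{sample}.j{n}", blocks))
                n += 1
        # decoys fully inside an exon
        for _ in range(spec.n_nonspanning):
            exon = m.exons[int(rng.integers(0, len(m.exons)))]
            s0 = exon.interval.start - 1
            width = min(60, exon.length)
            off = int(rng.integers(0, exon.length - width + 1))
            reads.append(SplicedRead(f"{sample}.x{n}", [(s0 + off, s0 + off + width)]))
            n += 1
        out[sample] = reads
    truth = {"depths": spec.depths, "gene_fpkm": spec.gene_fpkm}
    return out, truth


# ---------------------------------------------------------------------------
# Factorial expression matrix
# ---------------------------------------------------------------------------

GROUPS = [
    f"{sex}-{geno}-{organ}"
    for sex in ("M", "F")
    for geno in ("WT", "KO")
    for organ in ("Cb", "Br")
]


def simulate_expression(
    spec: ExpressionSpec | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """2x2x2 factorial matrix with planted cluster profiles + Gaussian noise.

    Returns (matrix probes x samples, design, truth).  Truth lists each
    probe's cluster ('null' for unaffected probes) and its planted per-group
    log2 offsets.  With the default two replicates the design has 16
    specimens, 8 per genotype.
    """
    spec = spec or ExpressionSpec()
    if spec.replicates < 2:
        raise ValueError("need >= 2 replicates per cell")
    rng = np.random.default_rng(seed)

    design_rows = []
    for g in GROUPS:
        sex, geno, organ = g.split("-")
        for r in range(1, spec.replicates + 1):
            design_rows.append(
                {"sample": f"{g}-{r}", "sex": sex, "genotype": geno,
                 "organ": organ, "replicate": r}
            )
    design = pd.DataFrame(design_rows)

    probes, clusters, offsets = [], [], []
    for cname, pattern in spec.patterns.items():
        for i in range(spec.probes_per_cluster):
            probes.append(f"p{cname}_{i:04d}")
            clusters.append(cname)
            offsets.append([pattern.get(g, 0.0) for g in GROUPS])
    for i in range(spec.n_null):
        probes.append(f"null_{i:05d}")
        clusters.append("null")
        offsets.append([0.0] * len(GROUPS))
    offsets_arr = np.array(offsets)

    lo, hi = spec.baseline_range
    baseline = rng.uniform(lo, hi, len(probes))
    cols, data = [], []
    for gi, g in enumerate(GROUPS):
        for r in range(1, spec.replicates + 1):
            cols.append(f"{g}-{r}")
            data.append(
                baseline + offsets_arr[:, gi]
                + rng.normal(0.0, spec.sigma, len(probes))
            )
    matrix = pd.DataFrame(np.column_stack(data), index=probes, columns=cols)
    matrix = matrix[design["sample"].tolist()]

    truth = pd.DataFrame({"probe": probes, "cluster": clusters}).set_index("probe")
    for gi, g in enumerate(GROUPS):
        truth[f"offset_{g}"] = offsets_arr[:, gi]
    return matrix, design, truth


def simulate_annotation(
    probes: Sequence[str],
    seed: int = 0,
    frac_riken: float = 0.1,
    frac_multi: float = 0.05,
    frac_nogene: float = 0.05,
) -> pd.DataFrame:
    """Probe -> gene-symbol annotation with planted curation categories."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, p in enumerate(probes):
        u = rng.random()
        if u < frac_nogene:
            genes, riken, cat = "", False, "no_gene"
        elif u < frac_nogene + frac_multi:
            genes, riken, cat = f"Gene{i}a;Gene{i}b", False, "multi_gene"
        elif u < frac_nogene + frac_multi + frac_riken:
            genes, riken, cat = f"{2000 + i}Rik", True, "riken"
        else:
            genes, riken, cat = f"Gene{i}", False, "single"
        rows.append({"probe": p, "genes": genes, "riken": riken, "category": cat})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Promoter sets with planted motifs
# ---------------------------------------------------------------------------

def builtin_motifs() -> dict[str, PWM]:
    """Synthetic nuclear-receptor-style PWMs (not database matrices).

    ERE-like: an inverted repeat GGTCA-nnn-TGACC; PPARG-like: a direct
    repeat AGGTCA-n-AGGTCA.  Strong positions carry 0.94 consensus weight.
    """

    def pwm(motif_id: str, consensus: str) -> PWM:
        cols = []
        for b in consensus:
            if b == "N":
                cols.append([0.25] * 4)
            else:
                col = [0.02] * 4
                col["ACGT".index(b)] = 0.94
                cols.append(col)
        return PWM(motif_id, np.array(cols).T)

    return {
        "ERE": pwm("ERE", "GGTCANNNTGACC"),
        "PPARG": pwm("PPARG", "AGGTCANAGGTCA"),
    }


def _consensus(pwm: PWM, rng: np.random.Generator) -> str:
    idx = pwm.matrix.argmax(axis=0)
    out = []
    for j, i in enumerate(idx):
        if np.allclose(pwm.matrix[:, j], 0.25):
            out.append(str(_BASES[rng.integers(0, 4)]))
        else:
            out.append("ACGT"[i])
    return "".join(out)


@dataclass
class PromoterFixture:
    genome: str
    chrom: str
    tss_table: pd.DataFrame
    gene_sets: dict[str, list[str]]
    truth: pd.DataFrame  # gene, set, planted
    pwm: PWM


def simulate_promoters(
    spec: PromoterSpec | None = None, seed: int = 0
) -> PromoterFixture:
    """One synthetic chromosome of promoters with planted motif prevalence.

    For each gene (spaced along the chromosome, random strand) a motif
    consensus is inserted somewhere inside TSS +/- flank with the set's
    prevalence; placement and truth are recorded per gene.
    """
    spec = spec or PromoterSpec()
    for s, p in spec.prevalence.items():
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence for {s} outside [0, 1]")
    rng = np.random.default_rng(seed)
    pwm = builtin_motifs()[spec.motif]

    genes, sets = [], []
    for sname, size in spec.set_sizes.items():
        for i in range(size):
            genes.append(f"{sname}_g{i:04d}")
            sets.append(sname)

    seq = _random_seq(rng, spec.gene_spacing * (len(genes) + 1))
    tss_rows, truth_rows = [], []
    for gi, (gene, sname) in enumerate(zip(genes, sets)):
        tss = spec.gene_spacing * (gi + 1)  # 1-based
        strand = "+" if rng.random() < 0.5 else "-"
        planted = bool(rng.random() < spec.prevalence[sname])
        if planted:
            site = _consensus(pwm, rng)
            if rng.random() < 0.5:
                from .gene_model import reverse_complement

                site = reverse_complement(site)
            lo = tss - spec.flank
            off = int(rng.integers(0, 2 * spec.flank + 1 - len(site)))
            seq[lo - 1 + off : lo - 1 + off + len(site)] = list(site)
        tss_rows.append(
            {"gene": gene, "chrom": spec.chrom, "position": tss, "strand": strand}
        )
        truth_rows.append({"gene": gene, "set": sname, "planted": planted})

    genome = "".join(seq)
    gene_sets = {s: [g for g, ss in zip(genes, sets) if ss == s] for s in spec.set_sizes}
    return PromoterFixture(
        genome,
        spec.chrom,
        pd.DataFrame(tss_rows),
        gene_sets,
        pd.DataFrame(truth_rows).set_index("gene"),
        pwm,
    )


def string_accessor(genome: str):
    """Sequence accessor over an in-memory chromosome string."""

    def get(iv: GenomicInterval) -> str:
        s0, e0 = iv.to_zero_based()
        return genome[s0:e0]

    return get
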