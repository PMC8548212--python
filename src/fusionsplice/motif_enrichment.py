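"""Promoter PWM scanning and gene-set enrichment by Pearson chi-square.

Nuclear-receptor response elements (ERE, PPARG, NRF1, CREB1, RARA...) are
scanned as position weight matrices over +/-1 kb promoter windows around
each gene's TSS, on both strands, scoring log-odds against a background
composition.  A gene "has" a motif when any window position on either strand
scores at or above the threshold (by default 80% of the motif's maximum
achievable log-odds).  Prevalence differences between gene sets are tested
with a df = 1 Pearson chi-square on the 2x2 presence table, without
continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import GenomicInterval, SequenceAccessor, reverse_complement

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PWM:
    """A motif as a 4 x L frequency matrix with log-odds scoring.

    ``matrix`` rows are A, C, G, T and columns sum to 1.  ``background`` is
    the per-base composition used in the denominator of the log-odds; a
    pseudocount regularises zero frequencies.  ``threshold_fraction`` is the
    default score-threshold policy (fraction of the maximum achievable
    log-odds score).
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds scores (pseudocounted), plus an all-zero N row."""
        p = (self.matrix + self.pseudocount) / (1 + 4 * self.pseudocount)
        return np.log2(p / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def default_threshold(self) -> float:
        return self.threshold_fraction * self.max_score

    def score(self, window: str) -> float:
        """Log-odds of one L-length window; N contributes 0."""
        lo = self.log_odds
        total = 0.0
        for j, base in enumerate(window.upper()):
            i = _BASE_INDEX.get(base)
            if i is not None:
                total += lo[i, j]
        return total


def read_jaspar(path_or_text: str) -> list[PWM]:
    """Parse JASPAR-style PFM text (counts or frequencies) into PWMs."""
    import io
    import os

    from Bio import motifs

    if os.path.exists(path_or_text):
        handle = open(path_or_text)
    else:
        handle = io.StringIO(path_or_text)
    with handle:
        records = motifs.parse(handle, "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        freqs = counts / counts.sum(axis=0)
        out.append(PWM(m.matrix_id or m.name, freqs))
    return out


# ---------------------------------------------------------------------------
# Promoter windows
# ---------------------------------------------------------------------------

@dataclass
class PromoterWindow:
    gene: str
    tss: int          # 1-based genomic position
    sequence: str     # strand-oriented
    flank: int
    clipped: bool = False


def extract_promoters(
    tss_table: pd.DataFrame,
    genome: SequenceAccessor,
    chrom_lengths: Mapping[str, int],
    flank: int = 1000,
) -> list[PromoterWindow]:
    """TSS +/- flank windows, strand-oriented; chromosome-end clipping flagged.

    ``tss_table`` columns: gene, chrom, position (1-based), strand.
    """
    out = []
    for row in tss_table.itertuples():
        L = chrom_lengths[row.chrom]
        if not (1 <= row.position <= L):
            raise ValueError(f"TSS of {row.gene} off chromosome {row.chrom}")
        start = max(1, row.position - flank)
        end = min(L, row.position + flank)
        clipped = (start != row.position - flank) or (end != row.position + flank)
        seq = genome(GenomicInterval(row.chrom, start, end))
        if row.strand == "-":
            seq = reverse_complement(seq)
        out.append(PromoterWindow(row.gene, row.position, seq.upper(), flank, clipped))
    return out


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3, anything else (incl. N) -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[arr]


def scan_pwm(
    window: PromoterWindow | str,
    pwm: PWM,
    threshold: float | None = None,
    both_strands: bool = True,
) -> pd.DataFrame:
    """All offsets scoring >= threshold, on one or both strands.

    Vectorised sliding-window log-odds; N bases contribute 0.  Offsets are
    0-based within the window's own orientation; minus-strand hits report the
    offset of the site's leftmost base in that same orientation.  Windows
    shorter than the motif yield an empty frame.
    """
    gene = window.gene if isinstance(window, PromoterWindow) else "."
    seq = window.sequence if isinstance(window, PromoterWindow) else window
    if threshold is None:
        threshold = pwm.default_threshold()
    L = pwm.length
    rows = []
    for strand, s in (("+", seq),) + ((("-", reverse_complement(seq)),) if both_strands else ()):
        if len(s) < L:
            continue
        enc = _encode(s)
        lo = np.vstack([pwm.log_odds, np.zeros(pwm.length)])  # row 4 = N
        win = np.lib.stride_tricks.sliding_window_view(enc, L)
        scores = lo[win, np.arange(L)].sum(axis=1)
        for off in np.flatnonzero(scores >= threshold):
            offset = int(off) if strand == "+" else len(seq) - L - int(off)
            rows.append(
                {
                    "gene": gene,
                    "motif": pwm.motif_id,
                    "offset": offset,
                    "strand": strand,
                    "score": float(scores[off]),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "motif", "offset", "strand", "score"])


def scan_promoters(
    windows: Iterable[PromoterWindow],
    pwms: Sequence[PWM],
    threshold: float | None = None,
) -> pd.DataFrame:
    frames = [f for f in (scan_pwm(w, p, threshold) for w in windows for p in pwms)
              if not f.empty]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene", "motif", "offset", "strand", "score"]
    )


# ---------------------------------------------------------------------------
# Presence + enrichment
# ---------------------------------------------------------------------------

def presence_table(
    hits: pd.DataFrame,
    gene_sets: Mapping[str, Iterable[str]],
    motif: str | None = None,
) -> pd.DataFrame:
    """Per-set motif-bearing gene fractions (a gene counts once).

    Returns one row per set: n_genes, n_with_motif, fraction, flag_empty.
    """
    h = hits if motif is None else hits[hits["motif"] == motif]
    bearing = set(h["gene"])
    rows = []
    for name, genes in gene_sets.items():
        genes = list(genes)
        with_motif = sum(g in bearing for g in genes)
        rows.append(
            {
                "set": name,
                "n_genes": len(genes),
                "n_with_motif": with_motif,
                "fraction": with_motif / len(genes) if genes else np.nan,
                "flag_empty": len(genes) == 0,
            }
        )
    return pd.DataFrame(rows).set_index("set")


def contingency_2x2(presence: pd.DataFrame, set_a: str, set_b: str) -> np.ndarray:
    """[[A with, A without], [B with, B without]] from a presence table."""
    rows = []
    for s in (set_a, set_b):
        w = int(presence.at[s, "n_with_motif"])
        n = int(presence.at[s, "n_genes"])
        rows.append([w, n - w])
    return np.array(rows, dtype=float)


@dataclass
class EnrichmentResult:
    table: np.ndarray
    chi2: float
    p_value: float
    proportions: tuple[float, float]


def chi_square_enrichment(table: np.ndarray) -> EnrichmentResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero marginal")
    chi2, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
    props = (
        table[0, 0] / table[0].sum(),
        table[1, 0] / table[1].sum(),
    )
    return EnrichmentResult(table, float(chi2), float(p), props)
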