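# Methods

## The locus model

The package models one gene whose transcription can initiate from three
first exons: the canonical first exon (E1), or a repeat-derived
simple-sequence-repeat exon (SSR) far upstream that splices either directly
onto the first common coding exon (E2) or through a short SINE-derived
cassette exon. All coordinates presented to users are 1-based inclusive
(the convention of printed genomic positions such as the
`chr5:51,912,715-51,912,718` deletion allele); internal arithmetic is
0-based half-open, with the conversion confined to `GenomicInterval`. Exon
sequences are stored genome-forward and reverse-complemented exactly once,
at splice assembly, so strand handling has a single testable location.

The elongation-time estimate is `hours = length_kb / rate_kb_min / 60`,
with a half-up display rounding to one decimal. The pre-mRNA length is an
explicit argument, never derived from the fixture model, because the
fixture compresses the real hundreds-of-kilobase introns (see below).

## Isoform templates and long-read classification

Candidate isoforms are materialised as template sequences. In `chains` mode
the enumerator emits every order-preserving exon subsequence from an
allowed start exon to the required terminal exon (required internals
forced, excluded ones dropped); for *s* start exons and *k* free internal
exons this yields exactly *s*·2^*k* templates, verified against an
exhaustive 2^*n* subset-filter oracle in the tests. `junction_pairs` mode
emits one minimal two-exon template per ordered pair. No particular
published template count is hard-coded: the count follows from the
constraints, which are configuration.

A long read supports a template when its alignment covers a breakpoint with
at least `min_overhang` (default 8 nt) aligned on both sides and the
alignment's MAPQ clears `min_mapq` (default 20). Reads are first trimmed by
`head_trim` (default 50 nt) and filtered at mean Phred ≥ 10; reads without
quality strings (consensus FASTA) pass the gate but are flagged. Because
all templates share their downstream exons, a read may legitimately pass on
several; it is assigned to the template whose spanned-junction set
(junctions identified by donor/acceptor exon pair) strictly contains every
other candidate's, and is otherwise `ambiguous`. A read is *full-length*
when it is at least `min_length_full` (default 2000 nt) long and spans every
junction of its assigned template; isoform proportions are taken over
full-length reads only. Junction coverage, not exon-terminus coverage, is
the full-length criterion; the distinction is documented rather than
guessed away.

Alignments can be supplied as SAM (pysam) or PAF. The built-in
`AnchorMatcher` places reads by exact k-mer anchors voting for a common
offset (k = 21, step 5). It assumes substitution-only errors — the
regime the read simulator produces by default — and reports a confidence
surrogate (60 when ≥ 3 anchors agree) rather than a calibrated MAPQ;
cross-template specificity is the resolver's job. For indel-rich data an
external aligner's SAM is the supported path.

## Junction quantification

A spliced short-read alignment increments a junction when one block ends on
the donor exon's last base and the next begins on the acceptor's first base,
each with ≥ `min_overhang` matched bases; a read spanning two junctions of
the same isoform increments both. "Counts per FPKM" is read as the
junction-spanning count divided by the locus-level FPKM of that sample
(FPKM is an input, not estimated here); the alternative reading — junction
counts themselves scaled per kb per million — is available via
`mode="per_kb_per_million"`. Samples with zero FPKM but nonzero counts are
flagged rather than silently dropped, as are all-zero samples in the share
computation. A mapping-quality floor is exposed (default 0) since whether
published junction counts used unique alignments only is not stated.

## ORF prediction and variant consequences

Translation uses the standard nuclear code (Biopython), with N-containing
codons as X; an independent hand-typed codon table serves as the oracle in
the tests. Start selection is positional (`annotated_starts`, `first_atg`,
`all_atgs`) — no Kozak scoring, since the biological argument is from
position and stop codons alone. Residues are attributed to the exon holding
the codon's **first** nucleotide; both headline counts
((448−362+1)/3 = 29 SSR residues and (65−48+1)/3 = 6 SINE residues) involve
junction-clean frames, so the attribution rule does not affect them and any
alternative would change only junction-split codons. N-terminal comparison
is a longest-common-suffix decomposition: novel = |new| − shared,
replaced = |reference| − shared.

Deletions are applied in transcript coordinates; the consequence call
re-translates from the original start, sets `frameshift` iff the deletion
length is not a multiple of 3 and lies at/after the start codon, and makes a
knock-out call when a frameshift truncates the ORF below 20% of its intact
length. The 20% threshold is a declared heuristic reported alongside the
raw evidence (truncated/intact lengths), not a biological claim.

## Factorial differential expression

The design is a 2³ full factorial (sex × genotype × organ), two replicates
per cell by default (16 specimens, 8 per genotype). Per probe, the omnibus
test is the F test of the saturated fixed-effects model, computed as the
one-way ANOVA across the 8 cells (algebraically identical), vectorised in
closed form and cross-checked against `scipy.stats.f_oneway`;
Benjamini–Hochberg adjustment runs across probes (statsmodels, with a
hand-rolled step-up oracle in the tests). Probes with zero within-cell
variance get an undefined p and a flag. Effect-size gates follow the
leverage/signal-to-noise framework's printed operating points as
configurable constants — FDR 0.05, |log₂FC| > 0.286 for SNR > 1 versus the
grand mean (any group), |log₂FC| > 0.094 for a 5% practical difference,
post hoc p < 0.05 — without re-deriving the upstream method. The post hoc
test is Welch's t (pooled-variance by flag): robust at 2–4 replicates,
though at n = 2 its ~2 denominator df make the full gate chain deliberately
conservative, which the analysis drivers report rather than hide.

Power analysis: for a planted 1.0 log₂-unit shift in one cell at σ = 0.25,
the omnibus noncentral-F power at n = 2/cell is 0.753 at α = 0.05 — before
FDR adjustment — so the package's power property is evaluated at n = 4/cell
(theoretical 0.9995 raw; ~0.98 after BH at ~10% signal density; empirical
0.99), while design-arithmetic checks keep the n = 2 study default. RMA (or
any) normalisation is upstream: the matrix is accepted as log2-scale
normalised intensities, with an optional quantile-normalisation utility.

PCA is centered sample-space PCA over the significant-probe matrix
(deterministic up to sign; near-zero-variance components dropped with a
rank flag). Pattern clustering is agglomerative with distance
1 − Pearson correlation of the 8 group-versus-grand-mean log₂FC profiles,
average linkage, cut at k = 4 to mirror the four reported pattern classes
(cut height configurable). Constant profiles have no defined correlation
and are rejected explicitly. With a fixed-k cut, a few false-positive
(noise-profile) probes inside a discovery set can claim clusters of their
own and merge correlated patterns — the n = 4 analysis driver demonstrates
and reports this failure mode.

## Motif enrichment

PWMs are 4×L frequency matrices (JASPAR text via Biopython) with
pseudocount 0.01 and a uniform background by default; scoring is log₂-odds,
vectorised over all window offsets on both strands, with N contributing 0.
The default threshold is 80% of the motif's maximum achievable score — a
declared convention, configurable as an absolute score. A gene "has" a
motif if any offset on either strand reaches the threshold (hits count once
per gene). Promoter windows are TSS ± 1 kb, strand-oriented, clipped at
chromosome ends with a flag. Enrichment between two gene sets is a df = 1
Pearson χ² on the 2×2 presence table without continuity correction; zero
marginals are an error, not a silent zero.

## Synthetic data: what it emulates, and what it does not

Every fixture is a pure function of (spec, seed). The mini-locus reproduces
the printed exon geometry exactly — SSR 448 nt with ATG at 362–364; SINE
65 nt with upstream-frame TGA at 19–21, a decoy ATG at 10–12, and the
initiating ATG at 48–50 encoding MDEGYF; E1 with a 48-nt CDS suffix
(16 residues); shared downstream exons sized so each named isoform's
transcript exceeds 2 kb — but compresses the real 566.7-kb and 200-kb
inter-exon distances to 5-kb spacers (recorded in the truth file), keeping
the genome ~75 kb. Construction scrubs unwanted ATGs/stops with
substitutions that provably cannot create new ones, then re-extracts and
verifies every planted codon.

Long reads are drawn from a configurable isoform mixture (default 60/25/15
favouring the SINE-containing fusion), with full-length probability 0.6,
fragments ≥ 500 nt, substitution errors at 2% by default, and 50 synthetic
head bases that the QC trim removes. Indels are deliberately absent by
default so the anchor matcher remains exact; this under-models real
long-read error structure, so passing tests demonstrate the classification
logic, not aligner robustness. Short junction reads are generated directly
as spliced alignments at planted depths per cell-type-like sample (neurons
SINE-dominated, astrocytes reference-only, progenitors mixed). The
expression simulator plants four shape-distinct KO-versus-WT patterns (up
in female cerebellum; up in both cerebella; down in male cerebellum; down
in both) at ~1 log₂-unit magnitude over a per-probe uniform(6, 10) baseline
with Gaussian σ = 0.25 noise — magnitudes within the span reported for real
pattern classes, chosen shape-distinct so recovery is identifiable
(ARI ≈ 0.96 at the defaults). Promoter fixtures plant an exact motif
consensus at the configured per-set prevalence (defaults 0.6 vs 0.2 over
200 genes/set) on a random strand within the window; the built-in ERE/PPARG
matrices are synthetic constructions in the style of nuclear-receptor
response elements, not database matrices. None of the generators emulate
microarray probe-level artefacts, platform error profiles, or real genome
annotation — conclusions about real data require real inputs.

## Problem sizes

Defaults keep everything desk-sized: a ~75-kb genome, 500 long reads,
~200 junction reads/sample, 2000 probes × 16–32 samples, 400 promoters of
2001 nt, 20–25 seeds for the enrichment power sweep. The full test suite
runs in about a minute; the acceptance script in well under one.
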