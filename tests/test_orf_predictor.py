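"""Fusion-ORF prediction, residue attribution, N-termini, deletion calls."""

import numpy as np
import pytest

from fusionsplice.gene_model import ModelError
from fusionsplice.orf_predictor import (
    OrfResult,
    TranscriptAnnotation,
    annotate_isoform,
    apply_deletion,
    compare_nterm,
    consequence,
    find_orfs,
    residues_from_exon,
)

CODON_TABLE = {  # independent oracle: hand-typed standard nuclear code
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


def _single_exon_tx(seq, starts=()):
    return TranscriptAnnotation(seq, ["X"], {"X": (0, len(seq))}, list(starts))


def _oracle_orfs(seq):
    """Brute-force 3-frame scan: every ATG, translate to first stop by table."""
    out = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        protein, stop = [], None
        for p in range(i, len(seq) - 2, 3):
            aa = CODON_TABLE.get(seq[p : p + 3], "X")
            if aa == "*":
                stop = p + 1
                break
            protein.append(aa)
        out.append((i + 1, stop, "".join(protein)))
    return out


class TestFindOrfs:
    def test_no_atg_first_atg_policy_empty(self):
        assert find_orfs(_single_exon_tx("CCCCCCGGG"), "first_atg") == []

    def test_ssr_frame_stops_inside_sine_and_sine_atg_opens_fusion_orf(self, model):
        tx = annotate_isoform(model, ["SSR", "SINE"] + [f"E{i}" for i in range(2, 14)])
        orfs = {o.start: o for o in find_orfs(tx, "annotated_starts")}
        sine0 = tx.boundaries["SINE"][0]
        ssr_orf = orfs[362]
        # the upstream (SSR) frame terminates at the TGA at SINE 19-21
        assert ssr_orf.stop == sine0 + 19
        assert ssr_orf.aa_length == 29 + 6
        # the second SINE ATG (48-50) reads through the downstream ORF
        sine_orf = orfs[sine0 + 48]
        assert not sine_orf.open_ended
        assert sine_orf.protein.startswith("MDEGYF")

    def test_all_atgs_matches_three_frame_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 300))))
            got = [(o.start, o.stop, o.protein) for o in
                   find_orfs(_single_exon_tx(seq), "all_atgs")]
            assert got == _oracle_orfs(seq)

    def test_n_codons_translate_to_x(self):
        tx = _single_exon_tx("ATGANTTAA")
        orf = find_orfs(tx, "first_atg")[0]
        assert orf.protein == "MX"

    def test_open_ended_orf_flagged(self):
        orf = find_orfs(_single_exon_tx("ATGAAAGCA"), "first_atg")[0]
        assert orf.open_ended and orf.stop is None

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            find_orfs(_single_exon_tx("ATGTAA"), "nonsense")

    def test_orf_length_identity_with_stop(self, model):
        tx = annotate_isoform(model, ["E1"] + [f"E{i}" for i in range(2, 14)])
        orf = find_orfs(tx, "annotated_starts")[0]
        assert 3 * orf.aa_length + 3 == orf.stop + 2 - orf.start + 1


class TestResidueAttribution:
    def test_ssr_contributes_29_novel_residues(self, model):
        tx = annotate_isoform(model, ["SSR"] + [f"E{i}" for i in range(2, 14)])
        orf = find_orfs(tx, "annotated_starts")[0]
        assert residues_from_exon(orf, "SSR", tx) == (448 - 362 + 1) // 3 == 29

    def test_sine_contributes_6_residues(self, model):
        tx = annotate_isoform(model, ["SSR", "SINE"] + [f"E{i}" for i in range(2, 14)])
        sine0 = tx.boundaries["SINE"][0]
        orf = {o.start: o for o in find_orfs(tx, "annotated_starts")}[sine0 + 48]
        assert residues_from_exon(orf, "SINE", tx) == (65 - 48 + 1) // 3 == 6

    def test_start_in_final_codon_gives_one_residue(self):
        tx = TranscriptAnnotation(
            "AAAATGGCACCC", ["X", "Y"], {"X": (0, 6), "Y": (6, 12)}, [(4, "annotated")]
        )
        orf = find_orfs(tx, "annotated_starts")[0]
        assert residues_from_exon(orf, "X", tx) == 1

    def test_unknown_exon_rejected(self, model):
        tx = annotate_isoform(model, ["E1", "E2"])
        orf = OrfResult(1, None, "M", ["E1"])
        with pytest.raises(ModelError):
            residues_from_exon(orf, "E99", tx)

    def test_residue_conservation_over_exons(self, model):
        for chain in (["E1"] + [f"E{i}" for i in range(2, 14)],
                      ["SSR", "SINE"] + [f"E{i}" for i in range(2, 14)]):
            tx = annotate_isoform(model, chain)
            for orf in find_orfs(tx, "annotated_starts"):
                total = sum(residues_from_exon(orf, e, tx) for e in chain)
                assert total == orf.aa_length


class TestNTermComparison:
    def test_identical_proteins(self):
        cmp = compare_nterm("MAGIC", "MAGIC")
        assert (cmp.novel, cmp.replaced) == (0, 0)

    def test_fixture_sine_vs_reference_6_replacing_16(self, model):
        ref_tx = annotate_isoform(model, ["E1"] + [f"E{i}" for i in range(2, 14)])
        ref = find_orfs(ref_tx, "annotated_starts")[0]
        fus_tx = annotate_isoform(model, ["SSR", "SINE"] + [f"E{i}" for i in range(2, 14)])
        sine0 = fus_tx.boundaries["SINE"][0]
        fus = {o.start: o for o in find_orfs(fus_tx, "annotated_starts")}[sine0 + 48]
        cmp = compare_nterm(fus.protein, ref.protein)
        assert (cmp.novel, cmp.replaced) == (6, 16)

    def test_matches_quadratic_suffix_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            a = "".join(rng.choice(aas, size=int(rng.integers(1, 30))))
            b = "".join(rng.choice(aas, size=int(rng.integers(1, 30))))
            # oracle: longest k with a[-k:] == b[-k:]
            k = max(
                (i for i in range(min(len(a), len(b)) + 1) if a[len(a) - i:] == b[len(b) - i:]),
            )
            cmp = compare_nterm(a, b)
            assert cmp.shared == k
            assert len(a) - cmp.novel == len(b) - cmp.replaced  # identity

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            compare_nterm("", "MA")


class TestDeletionConsequence:
    @pytest.fixture()
    def fusion(self, model):
        tx = annotate_isoform(model, ["SSR", "SINE"] + [f"E{i}" for i in range(2, 14)])
        sine0 = tx.boundaries["SINE"][0]
        orf = {o.start: o for o in find_orfs(tx, "annotated_starts")}[sine0 + 48]
        return tx, orf, sine0

    def test_tgaa_deletion_after_sine_atg_is_frameshift_ko(self, fusion):
        tx, orf, sine0 = fusion
        # the engineered allele removes TGAA just 3' of the SINE start codon
        dele = (sine0 + 53, sine0 + 56)
        assert tx.sequence[dele[0] - 1 : dele[1]] == "TGAA"
        after = apply_deletion(tx, *dele)
        cons = consequence(orf, after, dele)
        assert cons.frameshift
        assert cons.premature_stop is not None
        assert cons.ko_call
        assert cons.truncated_length < 0.2 * cons.intact_length

    def test_in_frame_3nt_deletion_shortens_by_one(self, fusion):
        tx, orf, sine0 = fusion
        dele = (sine0 + 51, sine0 + 53)  # one codon downstream of the ATG
        after = apply_deletion(tx, *dele)
        cons = consequence(orf, after, dele)
        assert not cons.frameshift
        assert cons.truncated_length == orf.aa_length - 1
        assert not cons.ko_call

    def test_deletion_5prime_of_start_leaves_protein_unchanged(self, fusion):
        tx, orf, sine0 = fusion
        dele = (10, 13)  # inside the SSR 5' UTR
        after = apply_deletion(tx, *dele)
        cons = consequence(orf, after, dele)
        new_start = orf.start - 4
        probe = TranscriptAnnotation(
            after.sequence, after.exon_chain, after.boundaries, [(new_start, "x")]
        )
        new_orf = find_orfs(probe, "annotated_starts")[0]
        assert new_orf.protein == orf.protein
        assert not cons.frameshift and cons.truncated_length == orf.aa_length

    def test_out_of_bounds_deletion_rejected(self, fusion):
        tx, _, _ = fusion
        with pytest.raises(IndexError):
            apply_deletion(tx, 0, 4)
        with pytest.raises(IndexError):
            apply_deletion(tx, len(tx.sequence), len(tx.sequence) + 3)

    def test_translation_matches_codon_table_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(3, 120)) // 3 * 3
            seq = "ATG" + "".join(rng.choice(list("ACGT"), size=n))
            orf = find_orfs(_single_exon_tx(seq), "first_atg")[0]
            expect = []
            for p in range(0, len(seq) - 2, 3):
                aa = CODON_TABLE[seq[p : p + 3]]
                if aa == "*":
                    break
                expect.append(aa)
            assert orf.protein == "".join(expect)
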