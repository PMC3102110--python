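"""Orientation, LSCFPS parsing, annotation, and mitochondrial removal."""

import numpy as np
import pytest

from coralscreen.codons import reverse_complement
from coralscreen.framecheck import (
    OrientationError,
    ValidatedPair,
    classify_annotation,
    extract_lscfps,
    filter_mitochondrial,
    orient_partner,
    stop_free_runs,
    validate_frame,
)
from coralscreen.io_core import TranscriptRecord, ValidationConfig
from coralscreen.pairing import translated_best_hit
from coralscreen.synthetic import (
    GeneTruth,
    default_codon_frequencies,
    make_transcripts,
    simulate_codon_pair,
    build_references,
)


def _random_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestOrientPartner:
    def _a(self, seq):
        return TranscriptRecord("a", seq, "A", orientation_known=True)

    def test_forward_partner_unchanged(self):
        rng = np.random.default_rng(0)
        shared = _random_nt(rng, 200)
        a = self._a(_random_nt(rng, 50) + shared + _random_nt(rng, 50))
        b = TranscriptRecord("b", shared + _random_nt(rng, 80), "B")
        oriented, strand = orient_partner(a, b)
        assert strand == "+" and oriented.seq == b.seq
        assert oriented.orientation_known

    def test_reverse_complemented_partner_flipped_back(self):
        rng = np.random.default_rng(1)
        shared = _random_nt(rng, 200)
        a = self._a(shared)
        b = TranscriptRecord("b", reverse_complement(shared + _random_nt(rng, 60)), "B")
        oriented, strand = orient_partner(a, b)
        assert strand == "-"
        assert shared in oriented.seq

    def test_unrelated_partner_is_unorientable(self):
        rng = np.random.default_rng(2)
        a = self._a(_random_nt(rng, 1000))
        b = TranscriptRecord("b", _random_nt(rng, 1000), "B")
        with pytest.raises(OrientationError):
            orient_partner(a, b)

    def test_unknown_orientation_anchor_rejected(self):
        a = TranscriptRecord("a", "ACGT" * 50, "A", orientation_known=False)
        b = TranscriptRecord("b", "ACGT" * 50, "B")
        with pytest.raises(ValueError, match="known orientation"):
            orient_partner(a, b)


class TestLscfps:
    def test_runs_ranked_by_length(self):
        runs = stop_free_runs("MA*KLLP*Q")
        assert runs[0][:1] == ("KLLP",)
        assert runs[1][:1] == ("MA",)
        assert runs[2][:1] == ("Q",)

    def test_no_stops_whole_string_first_second_empty(self):
        runs = stop_free_runs("MKWW")
        assert runs == [("MKWW", 1, 4)]

    def test_equal_length_tie_prefers_five_prime(self):
        runs = stop_free_runs("AB*CD")
        assert runs[0] == ("AB", 1, 2)
        assert runs[1] == ("CD", 4, 5)

    def test_matches_brute_force_scan_on_short_strings(self):
        # oracle: every maximal '*'-free substring found by position scan,
        # ranked by length with 5'-most first on ties
        rng = np.random.default_rng(3)
        for _ in range(40):
            s = "".join(rng.choice(list("MK*"), size=rng.integers(1, 30)))
            expected = sorted(
                ((part, i + 1, i + len(part)) for i, part in _runs_with_pos(s)),
                key=lambda t: (-len(t[0]), t[1]),
            )
            assert stop_free_runs(s) == expected

    def test_extract_from_hit_offsets_into_frame_translation(self):
        # alignment region starting at protein position 4 of the frame
        a = TranscriptRecord("a", "ATGATGATG" + "AAACCCGGGTTT" * 8, "A", True)
        b = TranscriptRecord("b", "AAACCCGGGTTT" * 8, "B", True)
        hit = translated_best_hit(a, [b], _zero_cutoff())
        (run, s, e), second = extract_lscfps(hit, "query")
        assert "*" not in run
        assert hit.query_prot_interval[0] <= s <= e <= hit.query_prot_interval[1]


def _runs_with_pos(s):
    pos = 0
    for part in s.split("*"):
        if part:
            yield pos, part
        pos += len(part) + 1


def _zero_cutoff():
    from coralscreen.io_core import PairingConfig

    return PairingConfig(min_bitscore=0.0)


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(4)
    pi = default_codon_frequencies()
    truths = [
        GeneTruth(f"g{i}", omega_true=0.3, kappa_true=2.0, t_true=0.1,
                  n_codons=150, is_trg=False)
        for i in range(4)
    ]
    ancestors = [simulate_codon_pair(g, pi, seed=20 + i)[2] for i, g in enumerate(truths)]
    prots, _ = build_references(truths, ancestors, seed=1)
    return truths, ancestors, prots


@pytest.fixture(scope="module")
def simulated_pair():
    pi = default_codon_frequencies()
    g = GeneTruth("g0", omega_true=0.3, kappa_true=2.0, t_true=0.12,
                  n_codons=250, is_trg=False, strand_b="-")
    cds_a, cds_b, anc = simulate_codon_pair(g, pi, seed=11)
    prots, mito = build_references([g], [anc], seed=11)
    ra, rb = make_transcripts(cds_a, cds_b, g, (20, 120), seed=11)
    return g, cds_a, cds_b, ra, rb, prots, mito


class TestClassifyAnnotation:
    def test_verbatim_translation_is_annotated(self, reference):
        truths, ancestors, prots = reference
        cls, hit, bits, ev = classify_annotation(ancestors[0], prots)
        assert cls == "annotated" and hit == "ref_g0"
        assert ev < 1e-20

    def test_random_protein_is_trg(self, reference):
        _, _, prots = reference
        rng = np.random.default_rng(5)
        random_prot = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=100))
        cls, hit, _, ev = classify_annotation(random_prot, prots, is_nucleotide=False)
        assert cls == "trg" and hit is None
        assert ev >= 1e-5

    def test_cutoff_is_strict(self, reference):
        _, _, prots = reference
        cfg = ValidationConfig(annot_evalue=0.0)  # nothing can be < 0
        cls, hit, _, _ = classify_annotation(prots[0].seq, prots, vcfg=cfg, is_nucleotide=False)
        assert cls == "trg"

    def test_empty_reference_yields_trg(self):
        cls, hit, bits, ev = classify_annotation("MKWVRD" * 20, [])
        assert cls == "trg" and hit is None


class TestValidateAndMito:
    def test_annotated_pair_accepted_with_true_frame(self, simulated_pair):
        g, cds_a, cds_b, ra, rb, prots, _ = simulated_pair
        b_oriented, strand = orient_partner(ra, rb)
        assert strand == "-"
        vp = validate_frame(ra, b_oriented, strand, prots)
        assert vp.rejection is None
        assert vp.annotation == "annotated" and vp.annotation_hit == "ref_g0"
        # ORF sits in the true reading frame of the embedded CDS
        idx = ra.seq.find(cds_a)
        assert (vp.orf_a_interval[0] - 1) % 3 == idx % 3
        assert vp.frame_a > 0 and vp.frame_b > 0

    def test_trg_pair_accepted_when_both_forward(self, simulated_pair):
        g, cds_a, cds_b, ra, rb, prots, _ = simulated_pair
        b_oriented, strand = orient_partner(ra, rb)
        vp = validate_frame(ra, b_oriented, strand, protein_ref=[])  # nothing annotates
        assert vp.annotation == "trg"
        assert vp.rejection is None
        assert vp.frame_a > 0 and vp.frame_b > 0

    def test_annotated_pair_hitting_wrong_reference_rejected(self, simulated_pair):
        g, cds_a, cds_b, ra, rb, prots, _ = simulated_pair
        # a reference containing a *different* gene: nucleotide-level hit
        # and LSCFPS hit cannot both point at it confidently
        pi = default_codon_frequencies()
        other = GeneTruth("gx", omega_true=0.3, kappa_true=2.0, t_true=0.1,
                          n_codons=250, is_trg=False)
        _, _, anc_other = simulate_codon_pair(other, pi, seed=77)
        other_prots, _ = build_references([other], [anc_other], seed=77)
        b_oriented, strand = orient_partner(ra, rb)
        vp = validate_frame(ra, b_oriented, strand, other_prots)
        # unrelated reference: the pair is treated as TRG, not annotated
        assert vp.annotation == "trg"

    def test_short_orf_rejected(self):
        pi = default_codon_frequencies()
        g = GeneTruth("g1", omega_true=0.3, kappa_true=2.0, t_true=0.1,
                      n_codons=100, is_trg=True)
        cds_a, cds_b, _ = simulate_codon_pair(g, pi, seed=13)
        ra, rb = make_transcripts(cds_a, cds_b, g, (0, 0), seed=13)
        cfg = ValidationConfig(min_orf_codons=150)
        b_oriented, strand = orient_partner(ra, rb, cfg)
        vp = validate_frame(ra, b_oriented, strand, [], cfg)
        assert vp.rejection == "short ORF"

    def test_mito_decoy_removed_clean_pair_kept(self, simulated_pair):
        g, cds_a, cds_b, ra, rb, prots, mito = simulated_pair
        decoy_seq = ra.seq + mito[0].seq[1000:1200]
        decoy = TranscriptRecord("decoy_a", decoy_seq, "A", True)
        vp_clean = ValidatedPair(id_a="g0_a", id_b="g0_b")
        vp_decoy = ValidatedPair(id_a="decoy_a", id_b="g0_b")
        b_oriented, _ = orient_partner(ra, rb)
        kept, removed = filter_mitochondrial(
            [(vp_clean, ra, b_oriented), (vp_decoy, decoy, b_oriented)], mito
        )
        assert removed == ["decoy_a"]
        assert [p.id_a for p in kept] == ["g0_a"]
        assert vp_decoy.rejection == "mitochondrial"
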