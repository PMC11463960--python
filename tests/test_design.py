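"""Stop-guide enumeration vs an exhaustive oracle; ranking and escape flags;
nuclease guide annotation."""

import pytest

from embryoedit.classify import classify_allele
from embryoedit.design import (
    StopGuideCandidate,
    alternative_start_offset,
    annotate_nuclease_guide,
    find_stop_guides,
    rank_candidates,
)
from embryoedit.genome import Amplicon, GuideRNA, TranscriptModel
from embryoedit.genotyper import apply_edits

STOPS = {"TAA", "TAG", "TGA"}


def oracle_candidates(amp):
    """Brute force: every offset x strand, NGG PAM, edit ALL window cytosines
    on the protospacer strand, re-translate the coding fragment in frame and
    flag premature in-frame stop gain. Single-segment phase-0 amplicons only."""
    seq = amp.sequence
    (lo, hi), = amp.cds_segments
    assert amp.cds_phase_at_start == 0
    wt_codons = [seq[lo + k : lo + k + 3] for k in range(0, hi - lo - 2, 3)]
    found = set()
    for i in range(len(seq) - 19):
        for strand in "+-":
            if strand == "+":
                if i + 23 > len(seq):
                    continue
                pam = seq[i + 20 : i + 23]
                if not (pam[1:] == "GG" and pam[0] in "ACGT"):
                    continue
                window = [i + k - 1 for k in range(4, 9)]
                edits = {p: "T" for p in window if seq[p] == "C"}
                start = i
            else:
                if i < 3:
                    continue
                pam_plus = seq[i - 3 : i]  # revcomp must be NGG -> CCN on plus
                if not (pam_plus[:2] == "CC" and pam_plus[2] in "ACGT"):
                    continue
                window = [i + 20 - k for k in range(4, 9)]
                edits = {p: "A" for p in window if seq[p] == "G"}
                start = i + 19
            if not edits:
                continue
            mutated = "".join(edits.get(p, seq[p]) for p in range(len(seq)))
            mut_codons = [
                mutated[lo + k : lo + k + 3] for k in range(0, hi - lo - 2, 3)
            ]
            gained = any(
                mc in STOPS and wc not in STOPS
                for mc, wc in zip(mut_codons, wt_codons)
            )
            if gained:
                found.add((strand, start))
    return found


def random_cds_amplicon(rng, n_codons=100):
    bases = list("ACGT")
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(bases) for _ in range(3))
        if c not in STOPS:
            codons.append(c)
    codons[0] = "ATG"
    flank = lambda: "".join(rng.choice(bases) for _ in range(30))
    cds = "".join(codons)
    return Amplicon("rand", flank() + cds + flank(), ((30, 30 + 3 * n_codons),), 0)


class TestFindStopGuides:
    def test_cag_with_c_at_window_position_6_yields_single_tag_candidate(self, rabbit):
        candidates = find_stop_guides(rabbit["amplicon"], "NGG", (4, 8))
        assert len(candidates) == 1
        c = candidates[0]
        assert c.original_codon == "CAG"
        assert c.converted_codon == "TAG"
        assert c.edited_strand == "sense"
        assert c.target_codon_index == 162
        assert c.bystander_cs == ()
        # the productive C sits at protospacer position 6
        assert c.edits[0].pos - c.guide.start + 1 == 6

    def test_no_window_cytosine_means_no_candidates(self):
        seq = "AT" * 20 + "AGG" + "AT" * 20
        amp = Amplicon("ac", seq, ((0, 30),), 0)
        assert find_stop_guides(amp) == []

    def test_matches_exhaustive_oracle_on_random_cds(self, rng):
        for _ in range(5):
            amp = random_cds_amplicon(rng)
            got = {(c.guide.strand, c.guide.start) for c in find_stop_guides(amp)}
            assert got == oracle_candidates(amp)

    def test_tgg_codon_edited_from_antisense_strand(self):
        # CDS of C/G-free filler, one CCA (minus-strand PAM) and one TGG whose
        # Gs fall in the window of the single minus-strand guide
        codons = ["ATT"] * 100
        codons[0] = "ATG"
        codons[15] = "CCA"  # plus positions 75-77: CC feeds the minus PAM at i=78
        codons[20] = "TGG"  # plus positions 90-92: Gs inside that guide's window
        seq = "T" * 30 + "".join(codons) + "T" * 30
        amp = Amplicon("tgg", seq, ((30, 330),), 0)
        candidates = find_stop_guides(amp)
        by_strand = {c.guide.strand for c in candidates}
        assert "-" in by_strand
        minus = next(c for c in candidates if c.guide.strand == "-")
        assert minus.edited_strand == "antisense"
        assert minus.original_codon == "TGG"
        assert minus.converted_codon in STOPS
        assert {(c.guide.strand, c.guide.start) for c in candidates} == (
            oracle_candidates(amp)
        )

    def test_candidates_replay_as_stop_ko_alleles(self, rng, rabbit):
        """Playing a candidate's edits through the classifier gives KO_stop."""
        amps = [rabbit["amplicon"]] + [random_cds_amplicon(rng) for _ in range(3)]
        seen = 0
        for amp in amps:
            for cand in find_stop_guides(amp):
                assert classify_allele(cand.edits, amp).value == "KO_stop"
                seen += 1
        assert seen > 0

    def test_single_c_mode_finds_the_rabbit_candidate(self, rabbit):
        candidates = find_stop_guides(rabbit["amplicon"], single_c=True)
        assert len(candidates) == 1
        assert len(candidates[0].edits) == 1


def _dummy_candidate(codon_index, guide_start=0):
    guide = GuideRNA("GATTACAGATTACAGATTAC", "AGG", "+", guide_start)
    return StopGuideCandidate(
        guide=guide,
        edits=(),
        target_codon_index=codon_index,
        original_codon="CAG",
        converted_codon="TAG",
        edited_strand="sense",
    )


class TestRankCandidates:
    def test_earlier_stop_ranks_first(self, rabbit):
        ranked = rank_candidates(
            [_dummy_candidate(163), _dummy_candidate(50, guide_start=5)],
            {"iso": rabbit["isoforms"]["rabbit-iso-a"]},  # single 360-aa isoform
        )
        assert [c.target_codon_index for c in ranked] == [50, 163]

    def test_truncation_fractions_match_division_oracle(self, rabbit):
        (cand,) = rank_candidates(
            find_stop_guides(rabbit["amplicon"]), rabbit["isoforms"]
        )
        by_iso = {t.isoform_id: t for t in cand.truncations}
        assert by_iso["rabbit-iso-a"].truncated_aa == 162
        assert by_iso["rabbit-iso-a"].truncation_fraction == pytest.approx(162 / 360)
        # alternative-start isoform begins at codon 100
        assert by_iso["rabbit-iso-b"].truncated_aa == 62
        assert by_iso["rabbit-iso-b"].truncation_fraction == pytest.approx(62 / 260)
        assert not cand.escape_risk

    def test_truncation_fraction_grows_with_stop_position(self, rabbit):
        ranked = rank_candidates(
            [_dummy_candidate(i, guide_start=i) for i in (120, 200, 300)],
            {"iso": rabbit["isoforms"]["rabbit-iso-a"]},
        )
        fracs = [c.truncations[0].truncation_fraction for c in ranked]
        assert fracs == sorted(fracs) and len(set(fracs)) == 3

    def test_stop_upstream_of_alternative_start_is_flagged_escape(self, rabbit):
        (ranked,) = rank_candidates([_dummy_candidate(50)], rabbit["isoforms"])
        by_iso = {t.isoform_id: t for t in ranked.truncations}
        assert by_iso["rabbit-iso-b"].escape
        assert ranked.escape_risk
        # the escaping isoform keeps its full length
        assert by_iso["rabbit-iso-b"].truncated_aa == 260

    def test_requires_isoforms(self):
        with pytest.raises(ValueError):
            rank_candidates([_dummy_candidate(10)], {})


class TestAlternativeStartOffset:
    def test_suffix_isoform(self):
        assert alternative_start_offset("MABCMDEF", "MDEF") == 4

    def test_canonical_is_offset_zero(self):
        assert alternative_start_offset("MABC", "MABC") == 0

    def test_non_methionine_isoform_rejected(self):
        with pytest.raises(ValueError):
            alternative_start_offset("MABC", "ABC")


class TestAnnotateNucleaseGuide:
    def test_bovine_guide_annotation(self, bovine):
        ann = annotate_nuclease_guide(
            bovine["guide"], bovine["amplicon"], bovine["transcript"],
            isoforms=bovine["isoforms"],
        )
        assert ann.cut_codon_index == 110
        assert ann.max_identical_prefix_aa == 110
        assert round(ann.max_percent_identity) == 22

    def test_noncoding_cut_rejected(self, bovine):
        amp = bovine["amplicon"]
        guide = GuideRNA(amp.sequence[0:20], amp.sequence[20:23], "+", 0)
        with pytest.raises(ValueError):
            annotate_nuclease_guide(guide, amp, bovine["transcript"])

    def test_consistent_with_protein_predictions(self, bovine):
        ann = annotate_nuclease_guide(
            bovine["guide"], bovine["amplicon"], bovine["transcript"]
        )
        for impact in ann.per_phase.values():
            assert impact.identical_prefix_aa <= ann.max_identical_prefix_aa
            assert impact.percent_identity_vs_wt <= ann.max_percent_identity + 1e-9
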