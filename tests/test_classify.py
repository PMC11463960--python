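"""Frame-rule allele classification, embryo genotype calls, protein impact."""

import itertools

import pytest
from hypothesis import given, strategies as st

from embryoedit.classify import (
    AlleleClass,
    call_embryo,
    classify_allele,
    epitope_retention,
    identical_prefix,
    predict_protein,
)
from embryoedit.genotyper import Edit
from embryoedit import fixtures as fx


class TestClassifyAllele:
    def test_three_bp_coding_insertion_is_in_frame(self, bovine):
        cls = classify_allele((fx.BOVINE_IF_EDIT,), bovine["amplicon"])
        assert cls.value == "IF" and cls.net_coding_delta == 3

    def test_one_bp_coding_insertion_is_frameshift_ko(self, bovine):
        cls = classify_allele((fx.BOVINE_KO1_EDIT,), bovine["amplicon"])
        assert cls.value == "KO_frameshift" and cls.net_coding_delta == 1

    def test_cag_to_tag_conversion_is_stop_ko(self, rabbit):
        cls = classify_allele((fx.RABBIT_STOP_EDIT,), rabbit["amplicon"])
        assert cls.value == "KO_stop"
        assert cls.first_novel_stop == 162  # global codon index of the stop

    def test_no_edits_is_wt(self, bovine):
        assert classify_allele((), bovine["amplicon"]).value == "WT"

    def test_noncoding_edit_is_wt_with_note(self, bovine):
        cls = classify_allele((Edit(5, "del", length=2),), bovine["amplicon"])
        assert cls.value == "WT" and "non-coding" in cls.note

    def test_in_frame_insertion_of_stop_codon_is_stop_ko(self, bovine):
        # multiple-of-three insertion that installs TAA: ORF is not conserved
        cls = classify_allele((Edit(100, "ins", seq="TAA"),), bovine["amplicon"])
        assert cls.value == "KO_stop"

    @pytest.mark.parametrize("delta", range(-9, 10))
    def test_class_depends_only_on_net_delta_mod3(self, delta, bovine):
        """Pure-indel alleles (no novel stop) follow the frame rule exactly."""
        amp = bovine["amplicon"]
        boundary = 100  # codon boundary inside the editing region
        if delta == 0:
            edits = ()
        elif delta > 0:
            edits = (Edit(boundary, "ins", seq="GCTGCTGCT"[:delta]),)
        else:
            edits = (Edit(boundary, "del", length=-delta),)
        cls = classify_allele(edits, amp)
        if delta % 3 != 0:
            assert cls.value == "KO_frameshift"
        elif delta == 0:
            assert cls.value == "WT"
        else:
            assert cls.value == "IF"

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=45, max_value=210),
                st.sampled_from(["ins", "del", "sub"]),
                st.integers(min_value=1, max_value=4),
            ),
            min_size=0,
            max_size=3,
        )
    )
    def test_frame_rule_is_total(self, bovine, spec):
        """Every non-overlapping edit set maps to exactly one class."""
        amp = bovine["amplicon"]
        edits, last_end = [], -1
        for pos, kind, size in sorted(spec):
            if pos <= last_end:
                continue
            if kind == "ins":
                edits.append(Edit(pos, "ins", seq="ACGT"[:size]))
                last_end = pos
            elif kind == "del":
                edits.append(Edit(pos, "del", length=size))
                last_end = pos + size
            else:
                alt = "A" if amp.sequence[pos] != "A" else "G"
                edits.append(Edit(pos, "sub", seq=alt))
                last_end = pos
        cls = classify_allele(tuple(edits), amp)
        assert cls.value in {"WT", "IF", "KO_frameshift", "KO_stop"}


WT = AlleleClass("WT")
IF = AlleleClass("IF", net_coding_delta=3)
KOF = AlleleClass("KO_frameshift", net_coding_delta=1)
KOS = AlleleClass("KO_stop")


class TestCallEmbryo:
    @pytest.mark.parametrize(
        "classes,expected",
        [
            ((KOF, KOF), "KO"),
            ((IF, KOF), "IF"),
            ((WT,), "WT"),
            ((WT, KOF), "IF"),  # an ORF-conserving allele rescues the embryo
            ((IF,), "IF"),
            ((KOF, KOS), "KO"),
        ],
    )
    def test_nuclease_calls(self, classes, expected):
        assert call_embryo(classes, "nuclease").call == expected

    @pytest.mark.parametrize(
        "classes,expected",
        [
            ((WT, KOS), "Hz"),
            ((KOS,), "KO"),
            ((KOS, KOS), "KO"),
            ((WT,), "WT"),
        ],
    )
    def test_base_editor_calls(self, classes, expected):
        assert call_embryo(classes, "base_editor").call == expected

    def test_empty_class_list_is_no_call(self):
        assert call_embryo((), "nuclease").call == "no-call"

    @given(
        st.lists(st.sampled_from([WT, IF, KOF, KOS]), min_size=1, max_size=4),
        st.permutations(range(4)),
    )
    def test_order_invariance_and_scheme_guards(self, classes, perm):
        shuffled = [classes[i % len(classes)] for i in perm][: len(classes)]
        for scheme in ("nuclease", "base_editor"):
            a = call_embryo(classes, scheme).call
            b = call_embryo(sorted(classes, key=lambda c: c.value), scheme).call
            assert a == b
        assert call_embryo(classes, "nuclease").call != "Hz"
        assert call_embryo(classes, "base_editor").call != "IF"


class TestPredictProtein:
    def test_wt_allele_is_identity(self, rabbit):
        imp = predict_protein((), rabbit["amplicon"], rabbit["transcript"])
        wt = rabbit["transcript"].protein
        assert imp.mutant_protein == wt
        assert imp.identical_prefix_aa == len(wt)
        assert imp.percent_identity_vs_wt == pytest.approx(100.0)

    def test_stop_at_codon_162_of_360_truncates_to_45_percent(self, rabbit):
        imp = predict_protein(
            (fx.RABBIT_STOP_EDIT,), rabbit["amplicon"], rabbit["transcript"]
        )
        assert len(imp.mutant_protein) == 162
        assert imp.truncation_fraction == pytest.approx(0.45)
        assert imp.identical_prefix_aa == 162

    def test_frameshift_keeps_110_aa_prefix_and_low_identity(self, bovine):
        """1-bp insertion at the cut: identical prefix 110 aa, ~22% identity."""
        imp = predict_protein(
            (fx.BOVINE_KO1_EDIT,), bovine["amplicon"], bovine["transcript"]
        )
        assert imp.identical_prefix_aa == 110
        assert imp.percent_identity_vs_wt < 25.0

    def test_in_frame_insertion_keeps_high_identity(self, bovine):
        imp = predict_protein(
            (fx.BOVINE_IF_EDIT,), bovine["amplicon"], bovine["transcript"]
        )
        assert imp.percent_identity_vs_wt > 99.0
        assert len(imp.mutant_protein) == len(bovine["transcript"].protein) + 1


class TestEpitopeRetention:
    def test_wt_vs_itself_is_full(self, rabbit):
        wt = rabbit["transcript"].protein
        assert epitope_retention(wt, wt, (150, 250)) == "full"

    def test_truncation_at_162_overlaps_partially(self, rabbit):
        wt = rabbit["transcript"].protein
        assert epitope_retention(wt, wt[:162], (150, 250)) == "partial"

    def test_truncation_at_100_retains_nothing(self, rabbit):
        wt = rabbit["transcript"].protein
        assert epitope_retention(wt, wt[:100], (150, 250)) == "none"

    def test_interval_beyond_wt_rejected(self, rabbit):
        wt = rabbit["transcript"].protein
        with pytest.raises(ValueError):
            epitope_retention(wt, wt, (350, 400))


def test_identical_prefix_basics():
    assert identical_prefix("MAB", "MAC") == 2
    assert identical_prefix("", "MA") == 0
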