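"""Frozen synthetic reference sequences used by the simulator and tests.

These stand in for the real loci (which would come from genome accessions):
a "bovine" exon-4-like nuclease target inside a 500-codon transcript and a
"rabbit" exon-8-like base-editor target inside a 360-codon transcript. They
are synthetic constructions engineered to carry, in miniature, the features
the pipeline exercises:

* bovine: a unique 20-nt protospacer with an AGG PAM whose blunt cut falls
  on the boundary of codon 110, so 1-bp/2-bp frameshift archetypes keep an
  identical N-terminal prefix of exactly 110 aa (22% of the 500-aa protein)
  before hitting engineered early stops in the shifted frames;
* rabbit: a CAG codon (codon index 162 of 360, i.e. 45% of protein length)
  whose cytosine sits at protospacer position 6 of the single NGG stop-guide
  candidate on the amplicon, with no bystander window cytosine;
* both transcripts carry an internal ATG (codons 30 and 100) that models an
  alternative-start isoform for the escape analysis.

Amplicons are 260 bp: 40 nt of non-coding flank, 180 nt of CDS, 40 nt flank.
"""

from __future__ import annotations

from .genome import Amplicon, GuideRNA, TranscriptModel, place_guide
from .genotyper import Edit

BOVINE_CDS = (
    "ATGACCAGTGGGTATCAGGGAATGCCGATACCATGCGTTGCGCCGAATAAACCCCATGTACCTCCCCATATA"
    "GTCAGCGCGGCCAATCTAATGCGGTCTCTATTTTGCTTACAACTGCCACTACCCCGGCAGGGGATTGACGTA"
    "AATACCCGTCTGGCCTGGGGTATATTGGCACTGTTCGTGTTCCAGGGCATGGGTGAGGCACTTAGCAACAAC"
    "AGGGTGGGAAAAGTACATCCGCACAAACTGCGGGAACAATGCGATATCCCTTCCTGTCAGCATAAAATTGAG"
    "AAGCAGAGAGGGATATGGACTCGATTGGCCTTTCGCAATTCTCGTAGGTTGAGACACCTAGTTTGGTTGGGT"
    "AAGCTGGCCAAGGCTTCATGTAAAAAGCAGCGACTCGACGGGACTGGCACATTAGCACATGGGCACACGATT"
    "GATTTCGGTGTTAACGCGTGGCTGGGATTAGCGAGACCCCTCCTCCCGACGGCGACCCAACGCACCCGCGAG"
    "ATGGAGGAATCCGTCGCCGCATGCAACCGAAAGGTGTGCGCCGAATCGCTATTCCACGGGGTGGATCTGAAC"
    "GCAATCGCTCCTATTTATTCAGTTATTTTCAGTCCGCGTGGCCGTTACTTTGAGATATCGTACAATGTCTTC"
    "AAACGGGTTTATTTCATATTCCATGCACATTTGTCTCGCCTCCCCACAATTGGCCCCTCGTTGCTTGCAATG"
    "CTCCGCTACAGTCAAAATCAACATATCAGAAAACAAGTCTGTACCACCCTATGCAAACGACTCACCGGGTGT"
    "CTTAGCAATGTCCCGCACCCCTTTCTGGAAATGGAACGTGAGAAGCGCTGGAGTCTCTTTGCGACCGCTCCC"
    "AAGAGACGCTCATCCACCAACAATAAGTTCACGTGGGCAACGTGGCGGAACGAGAGTACTGGGCAGGCGGCG"
    "ATGCAAGGCCGCTCGTCAGAAATCGGTTGGTCCTGTACCGTTAGATTCCATTTGTGCTCGCGTAAACCACAG"
    "TGCGAGATAAAGGGCTACGGTTGCTTATTATGCAGGCATAGGGGCCACCCATCCGGTAGCCAAGCCCTTTTG"
    "TGCATGAGTACCAGGACTTCTAAATACGAGTTGAGGGAGACGCCCCTCCGGGAATCTAGTAATGTGCAAGCG"
    "CTTCCCGGTCACGGAAGAGTCGTTCGTCCTCGTCGCGGAATGAATGTCGCTAAACTGCTGTTGGCTCTCATC"
    "TCATTTGACGCATACAGGACTCCACTATGTGTAGATGCGCCGAACAACCTCGTTGAAGATAGATGCATATCG"
    "TCTGCGCGCAGCCTCACGCACTGTCCGCTGTGTATTACGTCGGTATTGTCTTACCTGGGTGCTTCTGATCAC"
    "GTTTCGAGTCTGGAAGCCCAGCTTCCTGTAAGTCATCAGTGCGCCGGTATACTTTCTGTAAAGTTCTCGGTG"
    "AACAGAAGATACATGACCCGGCCGCATGTTGAGGGTGACTCGGCGGAAAGGGTGTTCCGGTAA"
)

BOVINE_AMPLICON_SEQ = (
    "GAGGGGAAGACCTACATACTTGATGCGAGGTGGCACAGCGTGTCAGCATAAAATTGAGAAGCAGAGAGGGAT"
    "ATGGACTCGATTGGCCTTTCGCAATTCTCGTAGGTTGAGACACCTAGTTTGGTTGGGTAAGCTGGCCAAGGC"
    "TTCATGTAAAAAGCAGCGACTCGACGGGACTGGCACATTAGCACATGGGCACACGATTGATTTCGGTGTTAA"
    "CGCGCAGCTTACATTGCTCGCTCGTACTGTGAATGGAACGGTGT"
)

RABBIT_CDS = (
    "ATGTGCCGTGAGCGGTTCGAAAGATCCGACTGGACGGAAATGTATCTCATTGGTACGTTTTTTTACAGTAAG"
    "CAGGATCTATTAAGTTTCAAGAATTGGAAGCATCATGGGCCCGATTTCTGTCTAGCCATGGACGTTTTAAGG"
    "GTATCTGGTGGGTATAGATGTTATAGGCTGGGGTTATGTTTTCATGGGTCCCCAATTCCTAGACGCGCCCAA"
    "GTCGCGAGCTTATCGGAGCAACCGGGGCATGTGGGAATCCTTTCATTAACCCCTGAAGAAATAACGTTGTAT"
    "CCCTCCTCAATGATGCCTACGCCGCCACGTTCACGCATCGTGCAGAATGTGGTGGTTTTTCTGATCAGACAA"
    "GAACCCAAGCCATGTGGTTTCCATTATCTATCTTGCAATCTGTATACACATTTTCTAGCATTCATAACTGCC"
    "TCGTATCCAAGATATATACACACGACAGACCCACATCATCGTCCCATAGGCTGTCAGCCGCGCGGACATAGG"
    "TCAATACCCTTCATATTTACGATAATATTCGCCAAGCAAAGTTGCCACGACACTAGCCCGTACACCAGCCTG"
    "TTTAGGTCGCGTACGGCGTGTGCCACCAGTAGCAATCCTGTCGATACACCACGCAGCTGCGTTAGAATGTTG"
    "TTTTATTCCAGAATTTTTCCCCTAGGCGCCCAAAATAGAGGGAGATTCATCCAGGACGGCAGTAAAGATCAG"
    "CCTCTTGAGTTTCGTGTTAAGACGGATGGGACACCGTATAGCCCGGTCACCATGTATTATTGCTGCGCGTCC"
    "CCGGGACCATTGGGAACGATGGAATCTCTGAGGGATCAGGAACCTGGATCACTGCCCGCGGTAAGTCGGTCA"
    "GTGAAGAGTGACACGGTTGCACCCTGGGGGTCCCTGGCGTTTGAACACTGTGAATTAGCGCATGATATTGCG"
    "GTGTACACGTCTGTGCTTGCGCGCCGATCCCAGCCACCCAAAGTTCACATTCGCCCTATTCCGTGGCGTGAA"
    "AGTCCGGTATCGGTTTCACTTTACACTCATTGTCGTGCGACCTCAAATGGAAAACATACGTACAGCGAACTG"
    "TGA"
)

RABBIT_AMPLICON_SEQ = (
    "ACAGGTAAAAATCTGGTCAGTCATGGAGACAATTTCCTTGTTCATAACTGCCTCGTATCCAAGATATATACA"
    "CACGACAGACCCACATCATCGTCCCATAGGCTGTCAGCCGCGCGGACATAGGTCAATACCCTTCATATTTAC"
    "GATAATATTCGCCAAGCAAAGTTGCCACGACACTAGCCCGTACACCAGCCTGTTTAGGTCGCGTACGGCGTG"
    "TGCCTATCAACGCATTCGACAGGAATTCCCTCAATGTTAGAACT"
)


def bovine_transcript() -> TranscriptModel:
    return TranscriptModel("bovine-tead4-like", BOVINE_CDS)


def bovine_amplicon() -> Amplicon:
    """Amplicon over CDS codons 90-150 with 40 nt flanks, phase 0."""
    return Amplicon(
        "bovine-ex4-amplicon", BOVINE_AMPLICON_SEQ, ((40, 220),), 0,
        cds_start_index=270,
    )


def bovine_guide() -> GuideRNA:
    amp = bovine_amplicon()
    (hit,) = place_guide(amp, amp.sequence[83:103], "NGG")
    return hit


def bovine_isoforms() -> dict[str, str]:
    """Canonical 500-aa protein plus the alternative-start (codon 30) isoform."""
    prot = bovine_transcript().protein
    return {"bovine-iso-a": prot, "bovine-iso-b": prot[30:]}


def rabbit_transcript() -> TranscriptModel:
    return TranscriptModel("rabbit-tead4-like", RABBIT_CDS)


def rabbit_amplicon() -> Amplicon:
    """Amplicon over CDS codons 140-200 with 40 nt flanks, phase 0."""
    return Amplicon(
        "rabbit-ex8-amplicon", RABBIT_AMPLICON_SEQ, ((40, 220),), 0,
        cds_start_index=420,
    )


def rabbit_guide() -> GuideRNA:
    amp = rabbit_amplicon()
    (hit,) = place_guide(amp, amp.sequence[101:121], "NGG")
    return hit


def rabbit_isoforms() -> dict[str, str]:
    """Canonical 360-aa protein plus the alternative-start (codon 100) isoform."""
    prot = rabbit_transcript().protein
    return {"rabbit-iso-a": prot, "rabbit-iso-b": prot[100:]}


# canonical allele archetypes, already in left-normalized form
BOVINE_IF_EDIT = Edit(98, "ins", seq="CTG")       # 3-bp in-frame insertion
BOVINE_KO1_EDIT = Edit(100, "ins", seq="A")       # 1-bp frameshift insertion
BOVINE_KO2_EDIT = Edit(97, "del", length=2)       # 2-bp frameshift deletion
BOVINE_KO3_EDIT = Edit(96, "del", length=1)       # 1-bp frameshift deletion
RABBIT_STOP_EDIT = Edit(106, "sub", seq="T")      # CAG -> TAG conversion
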