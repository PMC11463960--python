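"""Guide design for gene ablation: cytosine-base-editor stop installation
and annotation of conventional Cas9 frameshift guides.

A cytosine base editor (CBE, e.g. BE3) deaminates cytosines within a window
of the protospacer (canonically positions 4-8, PAM-distal) to thymines
without a double-strand break. Four codons can thereby become stops:
CAA->TAA, CAG->TAG, CGA->TGA through sense-strand C edits, and TGG (whose
Cs sit on the antisense strand) -> TGA/TAG/TAA through antisense edits.

The default editing model converts *all* window cytosines on the protospacer
strand simultaneously -- the worst-case bystander assumption, which is the
design-relevant one for a processive deaminase. A ``single_c`` mode edits
one cytosine at a time instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .classify import _novel_inframe_stops, predict_protein
from .genome import Amplicon, GuideRNA, TranscriptModel, pam_matches, revcomp, translate
from .genotyper import Edit, apply_edits


@dataclass
class IsoformTruncation:
    isoform_id: str
    start_codon_offset: int  # codon offset of the isoform start in the canonical CDS
    wt_length: int
    truncated_aa: int
    truncation_fraction: float
    escape: bool  # stop lies upstream of this isoform's alternative start


@dataclass
class StopGuideCandidate:
    guide: GuideRNA
    edits: tuple[Edit, ...]  # C->T substitutions in amplicon coordinates
    target_codon_index: int  # global codon index of the introduced stop
    original_codon: str
    converted_codon: str
    edited_strand: str  # "sense" | "antisense"
    bystander_cs: tuple[tuple[int, str], ...] = ()
    truncations: tuple[IsoformTruncation, ...] = ()

    @property
    def escape_risk(self) -> bool:
        return any(t.escape for t in self.truncations)


def _window_c_edits(guide: GuideRNA, sequence: str) -> tuple[Edit, ...]:
    """C->T edits (on the protospacer strand) for every window cytosine,
    expressed in plus-strand amplicon coordinates."""
    edits = []
    for pos in guide.window_positions():
        if not 0 <= pos < len(sequence):
            continue
        base = sequence[pos]
        if guide.strand == "+" and base == "C":
            edits.append(Edit(pos, "sub", seq="T"))
        elif guide.strand == "-" and base == "G":
            edits.append(Edit(pos, "sub", seq="A"))
    return tuple(sorted(edits))


def _codon_at(amplicon: Amplicon, sequence: str, fragment_codon: int) -> str:
    phase = amplicon.cds_phase_at_start
    lead = (3 - phase) % 3
    frag = "".join(sequence[s:e] for s, e in amplicon.cds_segments)
    k = fragment_codon * 3 + lead
    return frag[k : k + 3]


def find_stop_guides(
    amplicon: Amplicon,
    pam_pattern: str = "NGG",
    be_window: tuple[int, int] = (4, 8),
    single_c: bool = False,
) -> list[StopGuideCandidate]:
    """Enumerate every protospacer placement (both strands) whose window
    C->T edits install a premature in-frame stop codon.

    The amplicon should carry >= 23 nt of non-coding context on each side so
    placements whose PAM falls just outside the CDS are found.
    """
    seq = amplicon.sequence
    plen = len(pam_pattern)
    guides: list[GuideRNA] = []
    for i in range(len(seq) - 20 + 1):
        if i + 20 + plen <= len(seq) and pam_matches(pam_pattern, seq[i + 20 : i + 20 + plen]):
            guides.append(
                GuideRNA(seq[i : i + 20], seq[i + 20 : i + 20 + plen], "+", i,
                         be_window=be_window)
            )
        if i - plen >= 0 and pam_matches(pam_pattern, revcomp(seq[i - plen : i])):
            guides.append(
                GuideRNA(revcomp(seq[i : i + 20]), revcomp(seq[i - plen : i]),
                         "-", i + 19, be_window=be_window)
            )
    candidates: list[StopGuideCandidate] = []
    for guide in guides:
        all_edits = _window_c_edits(guide, seq)
        if not all_edits:
            continue
        edit_sets = [(e,) for e in all_edits] if single_c else [all_edits]
        for edits in edit_sets:
            cand = _evaluate(guide, edits, amplicon)
            if cand is not None:
                candidates.append(cand)
                break  # in single_c mode report the 5'-most productive C
    candidates.sort(key=lambda c: (c.target_codon_index, c.guide.start, c.guide.strand))
    return candidates


def _evaluate(
    guide: GuideRNA, edits: tuple[Edit, ...], amplicon: Amplicon
) -> StopGuideCandidate | None:
    stops = _novel_inframe_stops(edits, amplicon)
    if not stops:
        return None
    target = stops[0]
    offset_codon = (amplicon.cds_start_index or 0) // 3
    local = target - offset_codon - (1 if amplicon.cds_phase_at_start else 0)
    original = _codon_at(amplicon, amplicon.sequence, local)
    converted = _codon_at(amplicon, apply_edits(amplicon.sequence, edits), local)
    codon_span = {
        amplicon.cds_to_amplicon_index(i)
        for i in _fragment_indices(amplicon, local)
    }
    bystanders = []
    for e in edits:
        if e.pos not in codon_span:
            bystanders.append((e.pos, _consequence(e, amplicon)))
    return StopGuideCandidate(
        guide=guide,
        edits=edits,
        target_codon_index=target,
        original_codon=original,
        converted_codon=converted,
        edited_strand="sense" if guide.strand == "+" else "antisense",
        bystander_cs=tuple(bystanders),
    )


def _fragment_indices(amplicon: Amplicon, fragment_codon: int) -> list[int]:
    lead = (3 - amplicon.cds_phase_at_start) % 3
    k = fragment_codon * 3 + lead
    return [k, k + 1, k + 2]


def _consequence(edit: Edit, amplicon: Amplicon) -> str:
    idx = amplicon.amplicon_to_cds_index(edit.pos)
    if idx is None:
        return "non-coding"
    lead = (3 - amplicon.cds_phase_at_start) % 3
    if idx < lead:
        return "partial-codon"
    local = (idx - lead) // 3
    wt = _codon_at(amplicon, amplicon.sequence, local)
    mut = _codon_at(amplicon, apply_edits(amplicon.sequence, (edit,)), local)
    if len(wt) < 3:
        return "partial-codon"
    return "silent" if translate(wt) == translate(mut) else "missense"


def alternative_start_offset(canonical: str, isoform: str) -> int:
    """Codon offset of an isoform's start within the canonical protein.

    Isoforms produced from alternative downstream start sites are C-terminal
    suffixes of the canonical protein; the canonical itself has offset 0.
    """
    if not isoform.startswith("M"):
        raise ValueError("isoform protein lacks an initial methionine")
    if canonical.endswith(isoform):
        return len(canonical) - len(isoform)
    raise ValueError("isoform is not a C-terminal suffix of the canonical protein")


def rank_candidates(
    candidates: list[StopGuideCandidate],
    isoforms: dict[str, str],
) -> list[StopGuideCandidate]:
    """Attach per-isoform truncation metrics and order candidates.

    Sorting is ascending in the maximum truncation fraction across isoforms
    (earlier stops first). A candidate whose stop falls upstream of an
    isoform's alternative start is flagged: that isoform would still be
    produced intact, an escape route for the knockout.
    """
    if not isoforms:
        raise ValueError("at least one isoform protein is required")
    canonical = max(isoforms.values(), key=len)
    offsets = {}
    for iso_id, prot in isoforms.items():
        try:
            offsets[iso_id] = alternative_start_offset(canonical, prot)
        except ValueError:
            continue  # rejected isoform (no ATG / not a suffix); warn via omission
    ranked = []
    for cand in candidates:
        truncs = []
        for iso_id, off in offsets.items():
            prot = isoforms[iso_id]
            escape = cand.target_codon_index <= off
            truncated = len(prot) if escape else cand.target_codon_index - off
            truncs.append(
                IsoformTruncation(
                    isoform_id=iso_id,
                    start_codon_offset=off,
                    wt_length=len(prot),
                    truncated_aa=truncated,
                    truncation_fraction=truncated / len(prot),
                    escape=escape,
                )
            )
        ranked.append(replace(cand, truncations=tuple(truncs)))
    ranked.sort(
        key=lambda c: (
            max(t.truncation_fraction for t in c.truncations),
            c.guide.start,
        )
    )
    return ranked


@dataclass
class NucleaseGuideAnnotation:
    guide: GuideRNA
    cut_codon_index: int
    max_identical_prefix_aa: int
    max_percent_identity: float
    per_phase: dict = field(default_factory=dict)


def annotate_nuclease_guide(
    guide: GuideRNA,
    amplicon: Amplicon,
    transcript: TranscriptModel,
    isoforms: dict[str, str] | None = None,
) -> NucleaseGuideAnnotation:
    """Predict the frameshift outcome of a Cas9 nuclease guide.

    Applies 1-bp and 2-bp insertion archetypes at the blunt cut and reports,
    across both frameshift phases and all isoforms, the maximum identical
    N-terminal prefix and percent identity of the predicted truncated
    proteins -- the quantity that bounds how much WT protein a frameshift
    allele could still encode.
    """
    cut = guide.cut_site
    idx = amplicon.amplicon_to_cds_index(cut)
    if idx is None:
        raise ValueError("guide cut site is non-coding; frameshift annotation "
                         "requires a coding cut")
    offset = amplicon.cds_start_index or 0
    cut_codon = (offset + idx) // 3
    per_phase = {}
    max_prefix, max_ident = 0, 0.0
    for phase, ins in ((1, "A"), (2, "AT")):
        impact = predict_protein(
            (Edit(cut, "ins", seq=ins),), amplicon, transcript, isoforms=isoforms
        )
        per_phase[phase] = impact
        for rec in impact.isoforms:
            max_prefix = max(max_prefix, rec.identical_prefix_aa)
            max_ident = max(max_ident, rec.percent_identity_vs_wt)
    return NucleaseGuideAnnotation(
        guide=guide,
        cut_codon_index=cut_codon,
        max_identical_prefix_aa=max_prefix,
        max_percent_identity=max_ident,
        per_phase=per_phase,
    )
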