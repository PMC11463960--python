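"""Reading-frame classification of alleles and embryo genotype calls.

The frame rule: an allele whose edits change the coding length by a
non-multiple of three disrupts the open reading frame (KO by frameshift);
a multiple-of-three change conserves it (in-frame, IF) unless the edited
sequence gains a premature in-frame stop codon, and a substitution that
converts a codon into a stop (the cytosine-base-editor strategy, e.g.
CAG->TAG) is a KO in its own right.

Embryo calls aggregate allele classes per editing scheme:

* nuclease: WT (no edited allele), IF (>=1 edited allele and >=1 allele --
  edited or not -- conserving the ORF), KO (every allele disrupts the ORF);
* base editor: WT, Hz (mixture of ORF-conserving and stop alleles),
  KO (only stop alleles). The base-editor scheme never emits IF, the
  nuclease scheme never emits Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .genome import Amplicon, STOP_CODONS, TranscriptModel, translate
from .genotyper import Allele, Edit, apply_edits

WT = "WT"
IF = "IF"
KO_FRAMESHIFT = "KO_frameshift"
KO_STOP = "KO_stop"
HZ = "Hz"
KO = "KO"
NO_CALL = "no-call"


@dataclass(frozen=True)
class AlleleClass:
    value: str  # WT | IF | KO_frameshift | KO_stop
    net_coding_delta: int = 0
    first_novel_stop: int | None = None  # fragment codon index
    note: str = ""

    @property
    def is_ko(self) -> bool:
        return self.value in (KO_FRAMESHIFT, KO_STOP)

    @property
    def conserves_orf(self) -> bool:
        return self.value in (WT, IF)

    @property
    def edited(self) -> bool:
        return self.value != WT or self.note != ""


def _coding_net_delta(edit: Edit, amplicon: Amplicon) -> int:
    """Net coding-length change contributed by one edit."""
    if edit.kind == "ins":
        # inserted bases land inside the CDS when the insertion point has
        # coding sequence on both sides
        left_coding = edit.pos > 0 and amplicon.is_coding(edit.pos - 1)
        right_coding = edit.pos < len(amplicon) and amplicon.is_coding(edit.pos)
        return len(edit.seq) if (left_coding and right_coding) else 0
    if edit.kind == "del":
        coding = sum(
            1
            for p in range(edit.pos, edit.pos + edit.length)
            if amplicon.is_coding(p)
        )
        return -coding
    return 0


def _frame_trim(fragment: str, phase: int) -> str:
    """Trim a phase-offset coding fragment to whole codons of the WT frame."""
    lead = (3 - phase) % 3
    body = fragment[lead:]
    return body[: len(body) - len(body) % 3]


def _novel_inframe_stops(
    edits: tuple[Edit, ...], amplicon: Amplicon
) -> list[int]:
    """Fragment codon indices of premature stops gained in the WT frame.

    Only meaningful when the net coding delta is a multiple of three (the
    frame downstream of the edits is unchanged); for frameshifts the stop
    position is not knowable from the amplicon alone.
    """
    phase = amplicon.cds_phase_at_start
    wt = _frame_trim(amplicon.coding_fragment(), phase)
    edited_seq = apply_edits(amplicon.sequence, edits)
    # recompute segment intervals on the edited sequence
    shifted_segments = []
    for start, end in amplicon.cds_segments:
        shift_s = sum(_shift_before(e, start) for e in edits)
        shift_e = sum(_shift_before(e, end) for e in edits)
        shifted_segments.append((start + shift_s, end + shift_e))
    frag = "".join(edited_seq[s:e] for s, e in shifted_segments)
    mut = _frame_trim(frag, phase)
    lead_codon = (amplicon.cds_start_index or 0) // 3 + (1 if phase else 0)
    stops = []
    for k in range(0, len(mut) - 2, 3):
        codon = mut[k : k + 3]
        if codon in STOP_CODONS and (k >= len(wt) or wt[k : k + 3] not in STOP_CODONS):
            stops.append(lead_codon + k // 3)
    return stops


def _shift_before(edit: Edit, pos: int) -> int:
    """Coordinate shift induced at reference position ``pos`` by one edit."""
    if edit.kind == "ins":
        return len(edit.seq) if edit.pos <= pos else 0
    if edit.kind == "del":
        if edit.pos + edit.length <= pos:
            return -edit.length
        if edit.pos < pos:
            return -(pos - edit.pos)
    return 0


def classify_allele(
    allele: Allele | tuple[Edit, ...], amplicon: Amplicon
) -> AlleleClass:
    """Classify an allele by its reading-frame consequence."""
    edits = allele.edits if isinstance(allele, Allele) else tuple(allele)
    if not edits:
        return AlleleClass(WT)
    coding_edits = [e for e in edits if _touches_coding(e, amplicon)]
    if not coding_edits:
        return AlleleClass(WT, note="non-coding edit")
    note = ""
    if len(coding_edits) < len(edits):
        note = "partially non-coding allele"
    for e in edits:
        a, b = e.footprint()
        inside = [amplicon.is_coding(p) for p in range(max(a, 0), min(b, len(amplicon)))]
        if any(inside) and not all(inside):
            note = "edit spans a CDS segment boundary; classified from coding footprint"
    delta = sum(_coding_net_delta(e, amplicon) for e in coding_edits)
    if delta % 3 != 0:
        return AlleleClass(KO_FRAMESHIFT, net_coding_delta=delta, note=note)
    stops = _novel_inframe_stops(edits, amplicon)
    if stops:
        return AlleleClass(
            KO_STOP, net_coding_delta=delta, first_novel_stop=stops[0], note=note
        )
    return AlleleClass(IF, net_coding_delta=delta, note=note)


def _touches_coding(edit: Edit, amplicon: Amplicon) -> bool:
    if edit.kind == "ins":
        left = edit.pos > 0 and amplicon.is_coding(edit.pos - 1)
        right = edit.pos < len(amplicon) and amplicon.is_coding(edit.pos)
        return left and right
    a, b = edit.footprint()
    return any(amplicon.is_coding(p) for p in range(a, min(b, len(amplicon))))


@dataclass(frozen=True)
class EmbryoGenotype:
    call: str  # WT | IF | Hz | KO | no-call
    allele_classes: tuple[AlleleClass, ...]
    scheme: str


def call_embryo(
    allele_classes: list[AlleleClass] | tuple[AlleleClass, ...],
    scheme: str = "nuclease",
) -> EmbryoGenotype:
    """Aggregate allele classes into the embryo-level genotype call."""
    classes = tuple(allele_classes)
    if scheme not in ("nuclease", "base_editor"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if not classes:
        return EmbryoGenotype(NO_CALL, classes, scheme)
    any_edited = any(c.value != WT for c in classes)
    all_ko = all(c.is_ko for c in classes)
    any_conserving = any(c.conserves_orf for c in classes)
    if scheme == "nuclease":
        if not any_edited:
            call = WT
        elif all_ko:
            call = KO
        elif any_conserving:
            call = IF
        else:  # mixture of KO classes only is covered by all_ko above
            call = KO
    else:
        any_ko = any(c.is_ko for c in classes)
        if all_ko:
            call = KO
        elif any_ko:
            call = HZ
        else:
            call = WT
    return EmbryoGenotype(call, classes, scheme)


# ---------------------------------------------------------------------------
# protein impact


@dataclass(frozen=True)
class IsoformImpact:
    isoform_id: str
    wt_length: int
    mutant_length: int
    identical_prefix_aa: int
    percent_identity_vs_wt: float
    truncation_fraction: float


@dataclass(frozen=True)
class ProteinImpact:
    mutant_protein: str
    identical_prefix_aa: int
    percent_identity_vs_wt: float
    truncation_fraction: float
    isoforms: tuple[IsoformImpact, ...] = ()
    epitope_retained: dict = field(default_factory=dict)
    start_lost: bool = False


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    return aligner


def _identities(a: str, b: str) -> int:
    if not a or not b:
        return 0
    aln = _protein_aligner().align(a, b)[0]
    count = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        count += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    return count


def identical_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def mutant_cds(
    edits: tuple[Edit, ...], amplicon: Amplicon, transcript: TranscriptModel
) -> str:
    """Project amplicon edits onto the full transcript CDS."""
    if amplicon.cds_start_index is None:
        offset = transcript.locate_fragment(amplicon.coding_fragment())
    else:
        offset = amplicon.cds_start_index
    cds_edits = []
    for e in edits:
        if not _touches_coding(e, amplicon):
            continue
        if e.kind == "ins":
            idx = amplicon.amplicon_to_cds_index(e.pos)
            if idx is None:  # insertion at the right edge of a segment
                idx = amplicon.amplicon_to_cds_index(e.pos - 1) + 1
            cds_edits.append(Edit(offset + idx, "ins", seq=e.seq))
        elif e.kind == "del":
            coding = [
                amplicon.amplicon_to_cds_index(p)
                for p in range(e.pos, e.pos + e.length)
            ]
            coding = [c for c in coding if c is not None]
            cds_edits.append(Edit(offset + min(coding), "del", length=len(coding)))
        else:
            idx = amplicon.amplicon_to_cds_index(e.pos)
            cds_edits.append(Edit(offset + idx, "sub", seq=e.seq))
    return apply_edits(transcript.cds, tuple(cds_edits))


def predict_protein(
    allele: Allele | tuple[Edit, ...],
    amplicon: Amplicon,
    transcript: TranscriptModel,
    isoforms: dict[str, str] | None = None,
    epitopes: dict[str, tuple[int, int]] | None = None,
) -> ProteinImpact:
    """Predict the mutant protein and its homology to WT isoforms.

    Percent identity divides alignment identities by the WT isoform length,
    so truncations score low even when the retained prefix is a perfect
    match; the identical N-terminal prefix is reported separately.
    """
    edits = allele.edits if isinstance(allele, Allele) else tuple(allele)
    cds = mutant_cds(edits, amplicon, transcript)
    cds = cds[: len(cds) - len(cds) % 3]
    if not cds.startswith("ATG"):
        return ProteinImpact(
            mutant_protein="",
            identical_prefix_aa=0,
            percent_identity_vs_wt=0.0,
            truncation_fraction=0.0,
            start_lost=True,
        )
    mutant = translate(cds, until_stop=True)
    wt = transcript.protein
    iso_map = dict(isoforms or {})
    iso_map.setdefault(transcript.id, wt)
    records = []
    for iso_id, iso_prot in iso_map.items():
        ident = _identities(mutant, iso_prot)
        records.append(
            IsoformImpact(
                isoform_id=iso_id,
                wt_length=len(iso_prot),
                mutant_length=len(mutant),
                identical_prefix_aa=identical_prefix(mutant, iso_prot),
                percent_identity_vs_wt=100.0 * ident / len(iso_prot),
                truncation_fraction=len(mutant) / len(iso_prot),
            )
        )
    primary = next(r for r in records if r.isoform_id == transcript.id)
    impact = ProteinImpact(
        mutant_protein=mutant,
        identical_prefix_aa=primary.identical_prefix_aa,
        percent_identity_vs_wt=primary.percent_identity_vs_wt,
        truncation_fraction=primary.truncation_fraction,
        isoforms=tuple(records),
    )
    if epitopes:
        retained = {
            name: epitope_retention(wt, mutant, interval)
            for name, interval in epitopes.items()
        }
        object.__setattr__(impact, "epitope_retained", retained)
    return impact


def epitope_retention(
    wt_protein: str, mutant_protein: str, interval: tuple[int, int]
) -> str:
    """Retention of a 1-based inclusive WT residue interval in the mutant.

    ``full`` when every interval residue is identical at its position in the
    mutant, ``partial`` when some are, ``none`` when none is. Models whether
    an antibody raised against that immunogen could still detect the protein.
    """
    lo, hi = interval
    if not 1 <= lo <= hi <= len(wt_protein):
        raise ValueError(f"interval {interval} outside WT protein of length "
                         f"{len(wt_protein)}")
    same = [
        i < len(mutant_protein) and mutant_protein[i] == wt_protein[i]
        for i in range(lo - 1, hi)
    ]
    if all(same):
        return "full"
    if any(same):
        return "partial"
    return "none"
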