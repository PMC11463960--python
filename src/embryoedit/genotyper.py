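"""Edit calling and allele reconstruction from aligned amplicon reads.

Mirrors a deep-sequencing genotyping workflow for single embryos: reads are
aligned to the WT amplicon, per-read edits are extracted, left-normalized
(VCF convention) and restricted to the CRISPR editing region with a base
quality filter, and identical per-read edit lists are pooled into candidate
alleles kept above explicit support thresholds. Embryos are few-cell mosaics,
so more than two alleles are admissible; the thresholds are a noise floor,
not a ploidy prior.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .align import Alignment
from .genome import Amplicon

PHRED_OFFSET = 33


@dataclass(frozen=True, order=True)
class Edit:
    """A single called edit on the amplicon plus strand.

    ``pos`` is 0-based; for insertions it is the reference position of the
    base to the right of the inserted sequence. ``seq`` holds inserted bases
    (insertion) or the alternative base (substitution); ``length`` is the
    number of deleted bases (deletions only).
    """

    pos: int
    kind: str  # "ins" | "del" | "sub"
    seq: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del", "sub"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "sub" and len(self.seq) != 1:
            raise ValueError("substitutions carry exactly one alternative base")
        if self.kind == "del" and self.length < 1:
            raise ValueError("deletions need length >= 1")
        if self.kind == "ins" and not self.seq:
            raise ValueError("insertions need a non-empty sequence")

    @property
    def net_length(self) -> int:
        if self.kind == "ins":
            return len(self.seq)
        if self.kind == "del":
            return -self.length
        return 0

    def footprint(self) -> tuple[int, int]:
        """Half-open reference interval the edit touches (insertions span
        the two flanking bases so boundary insertions stay testable)."""
        if self.kind == "del":
            return self.pos, self.pos + self.length
        if self.kind == "ins":
            return max(self.pos - 1, 0), self.pos + 1
        return self.pos, self.pos + 1

    def hgvs(self) -> str:
        """Compact 1-based notation used in reports."""
        if self.kind == "ins":
            return f"g.{self.pos + 1}ins{self.seq}"
        if self.kind == "del":
            return f"g.{self.pos + 1}_{self.pos + self.length}del"
        return f"g.{self.pos + 1}>{self.seq}"


def left_normalize(edit: Edit, reference: str) -> Edit:
    """Shift an indel to its leftmost equivalent placement (VCF convention)."""
    if edit.kind == "ins":
        pos, seq = edit.pos, edit.seq
        while pos > 0 and seq[-1] == reference[pos - 1]:
            seq = reference[pos - 1] + seq[:-1]
            pos -= 1
        return Edit(pos, "ins", seq=seq)
    if edit.kind == "del":
        pos, length = edit.pos, edit.length
        while pos > 0 and reference[pos - 1] == reference[pos + length - 1]:
            pos -= 1
        return Edit(pos, "del", length=length)
    return edit


def apply_edits(reference: str, edits: tuple[Edit, ...] | list[Edit]) -> str:
    """Reference sequence with all edits applied; edits must not overlap."""
    ordered = sorted(edits, key=lambda e: (e.pos, e.kind != "ins"))
    for a, b in zip(ordered, ordered[1:]):
        if a.footprint()[1] > b.pos and not (a.kind == "ins" or b.kind == "ins"):
            raise ValueError(f"overlapping edits {a} / {b}")
    seq = reference
    for e in reversed(ordered):
        if e.kind == "ins":
            seq = seq[: e.pos] + e.seq + seq[e.pos :]
        elif e.kind == "del":
            seq = seq[: e.pos] + seq[e.pos + e.length :]
        else:
            seq = seq[: e.pos] + e.seq + seq[e.pos + 1 :]
    return seq


def quals_from_string(qual: str) -> list[int]:
    return [ord(c) - PHRED_OFFSET for c in qual]


def read_passes_qc(
    quals: list[int], min_base_q: int = 20, max_low_frac: float = 0.10
) -> bool:
    """Reads with more than ``max_low_frac`` low-quality bases are dropped."""
    if not quals:
        return False
    low = sum(q < min_base_q for q in quals)
    return low / len(quals) <= max_low_frac


def call_edits(
    alignment: Alignment,
    read: str,
    quals: list[int],
    reference: str,
    editing_region: tuple[int, int],
    min_base_q: int = 20,
) -> tuple[Edit, ...]:
    """Extract edits from an alignment, keeping only those whose normalized
    footprint overlaps ``editing_region`` (half-open amplicon interval).

    Substitutions additionally require base quality >= ``min_base_q``; bases
    read as N never seed a call.
    """
    lo, hi = editing_region
    edits: list[Edit] = []
    ref_pos = alignment.ref_start
    read_pos = 0
    for op, n in alignment.ops:
        if op == "M":
            for k in range(n):
                rb, qb = reference[ref_pos + k], read[read_pos + k]
                if rb != qb and qb != "N" and rb != "N":
                    if quals[read_pos + k] >= min_base_q:
                        edits.append(Edit(ref_pos + k, "sub", seq=qb))
            ref_pos += n
            read_pos += n
        elif op == "I":
            seq = read[read_pos : read_pos + n]
            if "N" not in seq:
                edits.append(
                    left_normalize(Edit(ref_pos, "ins", seq=seq), reference)
                )
            read_pos += n
        else:  # D
            edits.append(
                left_normalize(Edit(ref_pos, "del", length=n), reference)
            )
            ref_pos += n
    kept = []
    for e in edits:
        a, b = e.footprint()
        if a < hi and b > lo:  # overlap test on the normalized footprint
            kept.append(e)
    return tuple(sorted(kept))


@dataclass(frozen=True)
class Allele:
    """A reconstructed allele: an edit list with its read support."""

    edits: tuple[Edit, ...]
    support_reads: int
    support_fraction: float
    sequence: str

    @property
    def is_wt(self) -> bool:
        return not self.edits

    def hgvs(self) -> str:
        return ";".join(e.hgvs() for e in self.edits) if self.edits else "WT"


class NoCallError(RuntimeError):
    """Raised when an embryo yields no passing reads or no supported allele."""


def reconstruct_alleles(
    edit_lists: list[tuple[Edit, ...]],
    amplicon: Amplicon,
    min_support_reads: int = 5,
    min_support_fraction: float = 0.10,
) -> list[Allele]:
    """Pool identical per-read edit lists into alleles above support thresholds.

    Fractions are first computed against all passing reads, thresholds are
    applied, and the fractions of the reported alleles are renormalized. The
    WT (empty) edit list competes under the same thresholds.
    """
    n = len(edit_lists)
    if n == 0:
        raise NoCallError("no passing reads")
    counts = Counter(edit_lists)
    kept = {
        edits: c
        for edits, c in counts.items()
        if c >= min_support_reads and c / n >= min_support_fraction
    }
    if not kept:
        raise NoCallError("no allele above support thresholds")
    total = sum(kept.values())
    alleles = [
        Allele(
            edits=edits,
            support_reads=c,
            support_fraction=c / total,
            sequence=apply_edits(amplicon.sequence, edits),
        )
        for edits, c in kept.items()
    ]
    alleles.sort(key=lambda a: (-a.support_reads, a.edits))
    return alleles


def editing_region(
    guide, scheme: str = "nuclease", half_width: int = 10, window_pad: int = 2
) -> tuple[int, int]:
    """Default CRISPR editing region for a placed guide.

    Nuclease experiments use cut site +/- ``half_width``; base-editor
    experiments use the editing-window footprint padded by ``window_pad``.
    """
    if scheme == "nuclease":
        cut = guide.cut_site
        return cut - half_width, cut + half_width
    if scheme == "base_editor":
        lo, hi = guide.window_span()
        return lo - window_pad, hi + window_pad
    raise ValueError(f"unknown scheme {scheme!r}")
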