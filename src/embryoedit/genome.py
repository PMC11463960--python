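"""Core sequence model: amplicons, guides, transcripts, coordinates, translation.

Conventions used throughout the package:

* DNA is uppercase A/C/G/T (N tolerated in amplicon sequence, never in CDS).
* All coordinates are 0-based, half-open, on the amplicon plus strand.
* A guide's ``start`` is the amplicon offset of the protospacer 5' end *on its
  own strand* (so for a minus-strand guide it is the rightmost base in plus
  coordinates).
* The blunt SpCas9 cut is placed ``cut_offset`` bases from the protospacer
  3' end (default 3, i.e. between protospacer positions 17 and 18).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

_DNA = set("ACGT")
_DNA_N = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = {"TAA", "TAG", "TGA"}


class SequenceError(ValueError):
    """Raised for malformed DNA input (non-ACGT base, bad length, ...)."""


def clean_dna(seq: str, *, allow_n: bool = False, what: str = "sequence") -> str:
    """Uppercase and validate a DNA string.

    ``U`` is rejected explicitly: this is a DNA-only model. The position of
    the first offending character is reported.
    """
    seq = seq.upper()
    alphabet = _DNA_N if allow_n else _DNA
    for i, base in enumerate(seq):
        if base not in alphabet:
            if base == "U":
                raise SequenceError(
                    f"{what}: RNA base 'U' at position {i}; DNA input required"
                )
            raise SequenceError(f"{what}: invalid base {base!r} at position {i}")
    return seq


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, until_stop: bool = False) -> str:
    """Translate ``cds`` with the standard genetic code.

    A trailing incomplete codon is an error. With ``until_stop`` the returned
    protein stops just before the first stop codon; otherwise stops are
    rendered as ``*``.
    """
    cds = clean_dna(cds, what="cds")
    if len(cds) < 3:
        raise SequenceError(f"cds length {len(cds)} < 3")
    if len(cds) % 3:
        raise SequenceError(f"cds length {len(cds)} is not a multiple of 3")
    protein = str(Seq(cds).translate())
    if until_stop:
        stop = protein.find("*")
        if stop != -1:
            return protein[:stop]
    return protein


def pam_matches(pattern: str, site: str) -> bool:
    """``N`` in the pattern matches any real base; ``N`` in the site never matches."""
    if len(site) != len(pattern):
        return False
    for p, s in zip(pattern.upper(), site):
        if s not in _DNA:
            return False
        if p != "N" and p != s:
            return False
    return True


@dataclass(frozen=True)
class Amplicon:
    """A PCR amplicon with a lightweight CDS annotation.

    ``cds_segments`` are sorted, non-overlapping half-open intervals on the
    amplicon that lie in coding sequence. ``cds_phase_at_start`` is the codon
    position (0-2) of the first coding base. ``cds_start_index`` optionally
    anchors that base inside a full transcript CDS so edits can be projected
    onto whole-protein coordinates; it must agree with the phase.
    """

    id: str
    sequence: str
    cds_segments: tuple[tuple[int, int], ...] = ()
    cds_phase_at_start: int = 0
    cds_start_index: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", clean_dna(self.sequence, allow_n=True, what=self.id)
        )
        segs = tuple(tuple(s) for s in self.cds_segments)
        object.__setattr__(self, "cds_segments", segs)
        last = 0
        for start, end in segs:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"{self.id}: segment {(start, end)} out of bounds")
            if start < last:
                raise ValueError(f"{self.id}: segments unsorted or overlapping")
            last = end
        if self.cds_phase_at_start not in (0, 1, 2):
            raise ValueError("cds_phase_at_start must be 0, 1 or 2")
        if (
            self.cds_start_index is not None
            and self.cds_start_index % 3 != self.cds_phase_at_start
        ):
            raise ValueError("cds_start_index inconsistent with cds_phase_at_start")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def coding_length(self) -> int:
        return sum(end - start for start, end in self.cds_segments)

    def amplicon_to_cds_index(self, pos: int) -> int | None:
        """Fragment-local CDS index of an amplicon position, or None if non-coding."""
        if not 0 <= pos < len(self.sequence):
            raise IndexError(f"position {pos} outside amplicon of length {len(self)}")
        offset = 0
        for start, end in self.cds_segments:
            if start <= pos < end:
                return offset + (pos - start)
            offset += end - start
        return None

    def cds_to_amplicon_index(self, idx: int) -> int:
        if idx < 0:
            raise IndexError("negative CDS index")
        offset = 0
        for start, end in self.cds_segments:
            if idx < offset + (end - start):
                return start + (idx - offset)
            offset += end - start
        raise IndexError(f"CDS index {idx} beyond coding length {self.coding_length}")

    def is_coding(self, pos: int) -> bool:
        return self.amplicon_to_cds_index(pos) is not None

    def coding_fragment(self, sequence: str | None = None) -> str:
        """Concatenated coding sequence (of ``sequence`` if given, else the WT)."""
        seq = self.sequence if sequence is None else sequence
        return "".join(seq[start:end] for start, end in self.cds_segments)

    def codon_position(self, pos: int) -> int | None:
        """Codon position (0-2) of a coding amplicon base, honoring phase."""
        idx = self.amplicon_to_cds_index(pos)
        if idx is None:
            return None
        return (self.cds_phase_at_start + idx) % 3


@dataclass(frozen=True)
class GuideRNA:
    """A placed sgRNA. ``be_window`` is 1-based inclusive on the protospacer."""

    protospacer: str
    pam: str
    strand: str
    start: int
    cut_offset: int = 3
    be_window: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "protospacer", clean_dna(self.protospacer, what="protospacer")
        )
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        lo, hi = self.be_window
        if not 1 <= lo <= hi <= 20:
            raise ValueError("be_window must be within protospacer positions 1-20")

    @property
    def cut_site(self) -> int:
        """Amplicon plus-strand boundary of the blunt cut (between b-1 and b)."""
        n = len(self.protospacer)
        if self.strand == "+":
            return self.start + n - self.cut_offset
        return self.start - n + self.cut_offset + 1

    def window_span(self) -> tuple[int, int]:
        """Half-open plus-strand interval covered by the base-editing window."""
        lo, hi = self.be_window
        if self.strand == "+":
            return self.start + lo - 1, self.start + hi
        return self.start - hi + 1, self.start - lo + 2

    def window_positions(self) -> list[int]:
        """Plus-strand amplicon positions of the window, 5'->3' on the guide."""
        lo, hi = self.be_window
        if self.strand == "+":
            return [self.start + k - 1 for k in range(lo, hi + 1)]
        return [self.start - k + 1 for k in range(lo, hi + 1)]


def place_guide(
    amplicon: Amplicon, protospacer: str, pam_pattern: str = "NGG", **guide_kwargs
) -> list[GuideRNA]:
    """All exact placements of ``protospacer`` with an adjacent PAM, both strands."""
    protospacer = clean_dna(protospacer, what="protospacer")
    if len(protospacer) != 20:
        raise ValueError("protospacer must be 20 nt")
    seq = amplicon.sequence
    n, plen = len(seq), len(pam_pattern)
    hits: list[GuideRNA] = []
    for i in range(n - 20 + 1):
        if seq[i : i + 20] == protospacer and i + 20 + plen <= n:
            pam = seq[i + 20 : i + 20 + plen]
            if pam_matches(pam_pattern, pam):
                hits.append(
                    GuideRNA(protospacer, pam, "+", i, **guide_kwargs)
                )
    rc = revcomp(protospacer)
    for i in range(n - 20 + 1):
        if seq[i : i + 20] == rc and i - plen >= 0:
            pam = revcomp(seq[i - plen : i])
            if pam_matches(pam_pattern, pam):
                hits.append(
                    GuideRNA(protospacer, pam, "-", i + 19, **guide_kwargs)
                )
    return hits


@dataclass(frozen=True)
class TranscriptModel:
    """A full-length CDS and its protein; isoforms are labels plus sequences."""

    id: str
    cds: str
    isoform_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cds = clean_dna(self.cds, what=f"{self.id} cds")
        object.__setattr__(self, "cds", cds)
        if len(cds) % 3 or len(cds) < 6:
            raise ValueError(f"{self.id}: CDS length must be a multiple of 3")
        if not cds.startswith("ATG"):
            raise ValueError(f"{self.id}: CDS must start with ATG")
        prot = translate(cds)
        if not prot.endswith("*"):
            raise ValueError(f"{self.id}: CDS lacks a terminal stop codon")
        if "*" in prot[:-1]:
            raise ValueError(f"{self.id}: CDS contains an internal stop codon")

    @property
    def protein(self) -> str:
        return translate(self.cds, until_stop=True)

    def locate_fragment(self, fragment: str) -> int:
        """CDS index of a unique coding fragment (used to anchor amplicons)."""
        idx = self.cds.find(fragment)
        if idx == -1:
            raise ValueError(f"fragment not found in {self.id} CDS")
        if self.cds.find(fragment, idx + 1) != -1:
            raise ValueError(f"fragment is not unique in {self.id} CDS")
        return idx
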