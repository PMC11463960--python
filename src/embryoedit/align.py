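"""Affine-gap pairwise alignment of amplicon reads against the WT sequence.

The aligner is "glocal": the read must be aligned end to end, while unaligned
reference flanks (end gaps on the reference) are free. This matches how short
amplicon reads sit inside or around a reference amplicon. Gap scoring is
affine with a gap of length L costing ``gap_open + L * gap_extend``.

The dynamic program is Gotoh's three-state recurrence. Rows (reference
positions) are processed with NumPy; the within-row dependency of the
insertion state is resolved exactly with a running-maximum scan, so no band
or heuristic is involved. Tie-breaks are deterministic: diagonal (match or
mismatch) is preferred over a reference gap, which is preferred over a read
gap; gap placement is later canonicalized by left-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEG = -(10**8)


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    """Result of aligning one read to the amplicon.

    ``ops`` is a CIGAR-like list of ``(op, length)`` with op in {M, I, D};
    M covers both matches and mismatches, I consumes read only, D consumes
    reference only. ``ref_start`` is the first reference base consumed; the
    read is always consumed in full.
    """

    score: int
    ref_start: int
    ops: list[tuple[str, int]] = field(default_factory=list)

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.ops if op in "MD")

    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)


def align_read(
    read: str, reference: str, scoring: Scoring = DEFAULT_SCORING
) -> Alignment | None:
    """Align ``read`` to ``reference``; returns None for unalignable (all-N) reads."""
    if not read:
        raise ValueError("empty read")
    if set(read) <= {"N"}:
        return None
    ref = reference
    m, n = len(ref), len(read)
    go, ge = scoring.gap_open, scoring.gap_extend

    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    nn = ord("N")

    H = np.empty((m + 1, n + 1), dtype=np.int64)
    Hnf = np.empty_like(H)  # H before the insertion state is folded in
    E = np.empty_like(H)  # gap in read (deletion from reference)
    F = np.empty_like(H)  # gap in reference (insertion of read bases)

    j_idx = np.arange(n + 1)
    H[0] = go + ge * j_idx  # leading read bases as one insertion
    H[0, 0] = 0
    F[0] = H[0]
    F[:, 0] = NEG
    E[0] = NEG
    Hnf[0] = H[0]
    H[:, 0] = 0  # free leading reference gap

    for i in range(1, m + 1):
        rbase = ref[i - 1]
        if rbase == "N":
            sub = np.full(n, scoring.mismatch, dtype=np.int64)
        else:
            sub = np.where(
                (read_arr == ord(rbase)) & (read_arr != nn),
                scoring.match,
                scoring.mismatch,
            )
        E[i] = np.maximum(H[i - 1] + go + ge, E[i - 1] + ge)
        diag = H[i - 1, :-1] + sub
        hnf = np.maximum(diag, E[i, 1:])
        Hnf[i, 0] = 0
        Hnf[i, 1:] = hnf
        # F[i, j] = go + max_{k<j}(Hnf[i, k] - k*ge) + j*ge, exact affine scan
        run = np.maximum.accumulate(Hnf[i] - j_idx * ge)
        F[i, 1:] = go + run[:-1] + j_idx[1:] * ge
        H[i, 0] = 0
        H[i, 1:] = np.maximum(hnf, F[i, 1:])

    last_col = H[:, n]
    best = int(last_col.max())
    i = int(np.argmax(last_col))  # smallest index achieving the max

    # traceback
    ops_rev: list[str] = []
    j = n
    state = "H"
    while j > 0:
        if state == "H":
            if i == 0:
                state = "F"
                continue
            diag = H[i - 1, j - 1] + (
                scoring.match
                if ref[i - 1] == read[j - 1] and read[j - 1] != "N" and ref[i - 1] != "N"
                else scoring.mismatch
            )
            if H[i, j] == diag:
                ops_rev.append("M")
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops_rev.append("D")
            if E[i, j] == E[i - 1, j] + ge and i > 1:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:  # F
            ops_rev.append("I")
            if F[i, j] == Hnf[i, j - 1] + go + ge:
                j -= 1
                state = "H"
            else:
                j -= 1
    ref_start = i

    ops: list[tuple[str, int]] = []
    for op in reversed(ops_rev):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return Alignment(score=best, ref_start=ref_start, ops=ops)
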