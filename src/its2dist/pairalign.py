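"""Structure-aware global pairwise alignment of sequence-structure records.

Each alignment column is scored on the combined (nucleotide, structure
symbol) pair: a nucleotide match/mismatch term plus a structure
agreement/disagreement term on the 3-letter alphabet {(, ), .}, with affine
gap penalties (a gap run of length L costs open + (L-1) * extend).  This is
a documented, oracle-tested stand-in for synchronous sequence-structure
alignment; externally produced alignments can always be ingested instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqstruct import Alignment, SeqStructRecord

__all__ = ["ScoringScheme", "align_pair", "score_alignment"]

_NEG = -1e18


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 2.0
    mismatch: float = -1.0
    struct_agree: float = 1.0
    struct_disagree: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0 < self.match):
            raise ValueError("need gap_open <= gap_extend <= 0 < match")

    def column(self, nt_a: str, nt_b: str, sym_a: str, sym_b: str) -> float:
        nt = self.match if nt_a == nt_b else self.mismatch
        st = self.struct_agree if sym_a == sym_b else self.struct_disagree
        return nt + st


def score_alignment(aln: Alignment, s: ScoringScheme | None = None) -> float:
    """Additive column score of a 2-record alignment, affine gap runs included.

    Consistent with :func:`align_pair`'s objective; used as the brute-force
    oracle's scoring function.
    """
    s = s or ScoringScheme()
    if len(aln) != 2:
        raise ValueError("score_alignment needs exactly 2 records")
    a, b = aln[0], aln[1]
    total = 0.0
    in_gap_a = in_gap_b = False
    for nt_a, nt_b, sym_a, sym_b in zip(a.sequence, b.sequence, a.structure, b.structure):
        if nt_a == "-" and nt_b == "-":
            raise ValueError("all-gap column")
        if nt_a == "-":
            total += s.gap_extend if in_gap_a else s.gap_open
            in_gap_a, in_gap_b = True, False
        elif nt_b == "-":
            total += s.gap_extend if in_gap_b else s.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            total += s.column(nt_a, nt_b, sym_a, sym_b)
            in_gap_a = in_gap_b = False
    return total


def align_pair(
    a: SeqStructRecord, b: SeqStructRecord, s: ScoringScheme | None = None
) -> Alignment:
    """Global structure-aware alignment of two ungapped records (Gotoh DP).

    Maximises the additive combined score with affine gaps; ties are broken
    deterministically (diagonal, then up, then left).  Inserted gaps carry
    '-' in both the sequence and the structure string.
    """
    s = s or ScoringScheme()
    if "-" in a.sequence or "-" in b.sequence:
        raise ValueError("align_pair expects ungapped inputs")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sequence")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in b (consumes a; 'up')
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in a (consumes b; 'left')
    ptr_M = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_Ix = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_Iy = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = s.gap_open + (i - 1) * s.gap_extend
        ptr_Ix[i, 0] = 1
    for j in range(1, m + 1):
        Iy[0, j] = s.gap_open + (j - 1) * s.gap_extend
        ptr_Iy[0, j] = 2

    def argbest(candidates: list[float]) -> int:
        # preference order: M (diagonal source), Ix (up), Iy (left)
        best = 0
        for k in (1, 2):
            if candidates[k] > candidates[best]:
                best = k
        return best

    for i in range(1, n + 1):
        col_a, sym_a = a.sequence[i - 1], a.structure[i - 1]
        for j in range(1, m + 1):
            sub = s.column(col_a, b.sequence[j - 1], sym_a, b.structure[j - 1])
            cands = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            k = argbest(cands)
            M[i, j] = cands[k] + sub
            ptr_M[i, j] = k
            cands = [M[i - 1, j] + s.gap_open, Ix[i - 1, j] + s.gap_extend,
                     Iy[i - 1, j] + s.gap_open]
            k = argbest(cands)
            Ix[i, j] = cands[k]
            ptr_Ix[i, j] = k
            cands = [M[i, j - 1] + s.gap_open, Ix[i, j - 1] + s.gap_open,
                     Iy[i, j - 1] + s.gap_extend]
            k = argbest(cands)
            Iy[i, j] = cands[k]
            ptr_Iy[i, j] = k

    state = argbest([M[n, m], Ix[n, m], Iy[n, m]])
    i, j = n, m
    cols: list[tuple[str, str, str, str]] = []
    while i > 0 or j > 0:
        if state == 0:
            prev = ptr_M[i, j]
            cols.append((a.sequence[i - 1], b.sequence[j - 1],
                         a.structure[i - 1], b.structure[j - 1]))
            i, j = i - 1, j - 1
        elif state == 1:
            prev = ptr_Ix[i, j]
            cols.append((a.sequence[i - 1], "-", a.structure[i - 1], "-"))
            i -= 1
        else:
            prev = ptr_Iy[i, j]
            cols.append(("-", b.sequence[j - 1], "-", b.structure[j - 1]))
            j -= 1
        state = int(prev)
    cols.reverse()
    seq_a = "".join(c[0] for c in cols)
    seq_b = "".join(c[1] for c in cols)
    str_a = "".join(c[2] for c in cols)
    str_b = "".join(c[3] for c in cols)
    return Alignment((
        SeqStructRecord(a.id, seq_a, str_a),
        SeqStructRecord(b.id, seq_b, str_b),
    ))
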