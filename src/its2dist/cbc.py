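"""Compensatory base changes and raw stem/loop substitution rates.

A compensatory base change (CBC) at a consensus base pair is a change on
both sides with pairing maintained (e.g. AU -> GC); a hemi-CBC changes one
side only, again with pairing maintained (e.g. AU -> GU, the wobble
intermediate of the two-step CBC pathway).  Pairs whose end state is a
mismatch are neither: both labels require a structure-preserving state on
both sequences.  Wobble pairs GU/UG count as pairing.

SRS and SRL are the raw substitution rates of the two partitions — the
fraction of variable nucleotide columns in stems and loops respectively —
and their ratio SRS/SRL is the threshold statistic for deciding whether the
independent-site DNA model is still safe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import UndefinedRatioError
from .models import NT_STATES, PAIRING_STATES
from .seqstruct import Alignment, ConsensusStructure, PartitionMask, SeqStructRecord

__all__ = ["CBCCount", "RateRatio", "count_cbc", "substitution_rates",
           "variable_site_table"]

_NT = set(NT_STATES)


@dataclass(frozen=True)
class CBCCount:
    cbc: int
    hemi_cbc: int
    compared_pairs: int
    unscorable_pairs: int

    def __post_init__(self):
        if min(self.cbc, self.hemi_cbc, self.compared_pairs, self.unscorable_pairs) < 0:
            raise ValueError("negative counts")
        if self.cbc + self.hemi_cbc > self.compared_pairs:
            raise ValueError("cbc + hemi_cbc exceeds compared pairs")


@dataclass(frozen=True)
class RateRatio:
    """Raw substitution rates in stems (SRS) and loops (SRL)."""

    srs: float
    srl: float

    def __post_init__(self):
        if not (0 <= self.srs <= 1 and 0 <= self.srl <= 1):
            raise ValueError("rates must lie in [0, 1]")

    @property
    def ratio(self) -> float:
        if self.srl == 0:
            raise UndefinedRatioError("SRL is zero; SRS/SRL undefined")
        return self.srs / self.srl

    @property
    def ratio_or_none(self) -> Optional[float]:
        return None if self.srl == 0 else self.srs / self.srl


def classify_pair_change(s1: str, s2: str) -> str:
    """Classify an ordered dinucleotide change: 'cbc', 'hemi', or 'none'.

    Both end states must be pairing (canonical or wobble); a CBC changes both
    positions, a hemi-CBC exactly one.
    """
    if s1 not in PAIRING_STATES or s2 not in PAIRING_STATES:
        return "none"
    n_changed = int(s1[0] != s2[0]) + int(s1[1] != s2[1])
    if n_changed == 2:
        return "cbc"
    if n_changed == 1:
        return "hemi"
    return "none"


def count_cbc(a: SeqStructRecord, b: SeqStructRecord, cons: ConsensusStructure) -> CBCCount:
    """Count CBCs and hemi-CBCs between two aligned records on the consensus
    pairs.  Pairs containing a gap or ambiguity in either record are
    unscorable.  Symmetric in its two arguments."""
    if len(a) != len(b):
        raise ValueError("records are not aligned to common columns")
    cbc = hemi = compared = unscorable = 0
    for i, j in sorted(cons.pairs):
        if j >= len(a):
            raise ValueError(f"consensus pair ({i},{j}) outside alignment")
        nts = (a.sequence[i], a.sequence[j], b.sequence[i], b.sequence[j])
        if not all(n in _NT for n in nts):
            unscorable += 1
            continue
        compared += 1
        kind = classify_pair_change(nts[0] + nts[1], nts[2] + nts[3])
        if kind == "cbc":
            cbc += 1
        elif kind == "hemi":
            hemi += 1
    return CBCCount(cbc, hemi, compared, unscorable)


def substitution_rates(aln2: Alignment, mask: PartitionMask) -> RateRatio:
    """Raw per-column substitution rates between two sequences.

    SRS = differing stem nucleotide columns / usable stem columns (gapped
    columns deleted); SRL analogous over loops.  The ratio property raises
    when SRL = 0 (the loops-invariant case excluded from RNA analysis).
    """
    if len(aln2) != 2:
        raise ValueError("substitution_rates needs exactly 2 records")
    if mask.columns != aln2.columns:
        raise ValueError("mask/alignment length mismatch")
    a, b = aln2[0].sequence, aln2[1].sequence

    def rate(cols: list[int]) -> float:
        usable = [c for c in cols if a[c] in _NT and b[c] in _NT]
        if not usable:
            return 0.0
        return sum(1 for c in usable if a[c] != b[c]) / len(usable)

    return RateRatio(srs=rate(mask.stem_columns), srl=rate(mask.loop_columns))


def variable_site_table(aln: Alignment, mask: PartitionMask) -> dict[str, int]:
    """Variable-site counts per partition.

    A column is variable iff at least two distinct non-gap nucleotides occur
    among the records.  Returns stem/loop variable counts and totals.
    """
    if mask.columns != aln.columns:
        raise ValueError("mask/alignment length mismatch")

    def variable(col: int) -> bool:
        seen = {r.sequence[col] for r in aln.records} & _NT
        return len(seen) >= 2

    stem_var = sum(1 for c in mask.stem_columns if variable(c))
    loop_var = sum(1 for c in mask.loop_columns if variable(c))
    return {
        "stem_variable": stem_var,
        "loop_variable": loop_var,
        "total_variable": stem_var + loop_var,
        "stem_columns": len(mask.stem_columns),
        "loop_columns": len(mask.loop_columns),
    }
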