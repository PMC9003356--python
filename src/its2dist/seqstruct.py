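"""Sequence-structure records, Vienna I/O, consensus structures and partitions.

The unit of analysis is a nucleotide sequence together with its secondary
structure in dot-bracket notation (Vienna format: three lines per record —
``>id``, sequence, structure).  Alignments of such records are partitioned
into paired (stem) and unpaired (loop) columns via a majority-rule consensus
structure, which is the basis of every downstream paired-site analysis.

Coordinates are 0-based throughout the API; user-facing reports are 1-based.
"""

from __future__ import annotations

import io as _io
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import StructureError, ViennaFormatError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU-")
STRUCT_ALPHABET = frozenset("().-")

__all__ = [
    "SeqStructRecord",
    "Alignment",
    "ConsensusStructure",
    "PartitionMask",
    "Role",
    "pair_table",
    "read_vienna",
    "write_vienna",
    "read_fasta",
    "write_fasta",
    "consensus_structure",
    "partition_alignment",
]


def pair_table(structure: str) -> list[Optional[int]]:
    """Map each column of a dot-bracket string to its partner (or None).

    '.' and '-' columns map to None.  Raises :class:`StructureError` with the
    offending column on unbalanced input.
    """
    partners: list[Optional[int]] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at column {i}", column=i)
            j = stack.pop()
            partners[j] = i
            partners[i] = j
        elif ch in ".-":
            continue
        else:
            raise StructureError(f"illegal structure character {ch!r} at column {i}", column=i)
    if stack:
        raise StructureError(
            f"unmatched '(' opened at column {stack[-1]} (end of string)",
            column=len(structure),
        )
    return partners


@dataclass(frozen=True)
class SeqStructRecord:
    """One RNA sequence plus its dot-bracket secondary structure."""

    id: str
    sequence: str
    structure: str

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ViennaFormatError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ViennaFormatError(f"record {self.id!r}: illegal sequence characters {sorted(bad)}")
        pair_table(self.structure)  # validates balance and alphabet
        for i, (nt, sym) in enumerate(zip(self.sequence, self.structure)):
            if nt == "-" and sym not in ".-":
                raise ViennaFormatError(
                    f"record {self.id!r}: gap at column {i} carries structure symbol {sym!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        """Set of (i, j), i < j, base-pair columns of this record."""
        pt = pair_table(self.structure)
        return {(i, j) for i, j in enumerate(pt) if j is not None and i < j}

    def ungapped(self) -> "SeqStructRecord":
        """Drop gap columns (used before re-alignment)."""
        keep = [i for i, nt in enumerate(self.sequence) if nt != "-"]
        return SeqStructRecord(
            self.id,
            "".join(self.sequence[i] for i in keep),
            "".join(self.structure[i] for i in keep),
        )


@dataclass(frozen=True)
class Alignment:
    """An ordered list of equal-length sequence-structure records."""

    records: tuple[SeqStructRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"records have unequal aligned lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")

    @property
    def columns(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> SeqStructRecord:
        return self.records[i]

    def subset(self, ids: Sequence[str]) -> "Alignment":
        wanted = set(ids)
        return Alignment(tuple(r for r in self.records if r.id in wanted))


def _normalize_seq(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def read_vienna(text: str) -> list[SeqStructRecord]:
    """Parse Vienna-format text: repeating (>id, sequence, structure) lines.

    DNA input is accepted: T is silently mapped to U.
    """
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    if len(lines) % 3 != 0:
        raise ViennaFormatError(
            f"Vienna text has {len(lines)} non-empty lines; expected a multiple of 3"
        )
    records = []
    for k in range(0, len(lines), 3):
        header, seq, struct = lines[k], lines[k + 1], lines[k + 2]
        if not header.startswith(">"):
            raise ViennaFormatError(f"expected '>' header, got {header!r}")
        rid = header[1:].split()[0] if header[1:].strip() else f"record_{k // 3}"
        try:
            records.append(SeqStructRecord(rid, _normalize_seq(seq), struct.strip()))
        except StructureError as e:
            raise StructureError(f"record {rid!r}: {e}", column=e.column) from e
    return records


def write_vienna(records: Iterable[SeqStructRecord]) -> str:
    """Serialize records as Vienna text, one line per field."""
    out = []
    for r in records:
        out.append(f">{r.id}\n{r.sequence}\n{r.structure}\n")
    return "".join(out)


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Read plain FASTA into (id, sequence) tuples, T mapped to U."""
    return [
        (rec.id, _normalize_seq(str(rec.seq)))
        for rec in SeqIO.parse(_io.StringIO(text), "fasta")
    ]


def write_fasta(records: Iterable[SeqStructRecord | tuple[str, str]]) -> str:
    out = _io.StringIO()
    seqrecs = []
    for r in records:
        rid, seq = (r.id, r.sequence) if isinstance(r, SeqStructRecord) else r
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecs, out, "fasta-2line")
    return out.getvalue()


@dataclass(frozen=True)
class ConsensusStructure:
    """A set of non-crossing consensus base pairs over alignment columns."""

    pairs: frozenset[tuple[int, int]]
    threshold: float = 0.75

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        if not (0.5 < self.threshold <= 1.0):
            raise ValueError("consensus threshold must lie in (0.5, 1.0]")
        cols: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j):
                raise ValueError(f"invalid pair ({i},{j})")
            if i in cols or j in cols:
                raise ValueError(f"column appears in two pairs: ({i},{j})")
            cols.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1:]:
                if i < k < j < l:
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")

    def to_dotbracket(self, columns: int) -> str:
        s = ["."] * columns
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)


def _crosses(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((p, q))
    return i < k < j < l


def consensus_structure(aln: Alignment, threshold: float = 0.75) -> ConsensusStructure:
    """Majority-rule consensus base pairs of an alignment.

    A candidate pair (i, j) is retained when the fraction of records pairing
    columns i and j — among records ungapped at both columns — reaches
    ``threshold``, with at least 2 ungapped supporting records.  Conflicting
    (column-sharing or crossing) candidates are removed greedily in decreasing
    frequency order, ties broken by smaller i then smaller j.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("consensus threshold must lie in (0.5, 1.0]")
    if all(set(r.structure) <= {".", "-"} and set(r.sequence) <= {"-"} for r in aln.records):
        raise ValueError("no structures present in alignment")
    support: Counter[tuple[int, int]] = Counter()
    for r in aln.records:
        support.update(r.pairs)
    candidates: list[tuple[float, tuple[int, int], int]] = []
    for (i, j), n_sup in support.items():
        denom = sum(
            1 for r in aln.records if r.sequence[i] != "-" and r.sequence[j] != "-"
        )
        if denom == 0 or n_sup < 2:
            continue
        freq = n_sup / denom
        if freq >= threshold:
            candidates.append((freq, (i, j), n_sup))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    accepted: list[tuple[int, int]] = []
    used_cols: set[int] = set()
    for _freq, pair, _n in candidates:
        i, j = pair
        if i in used_cols or j in used_cols:
            continue
        if any(_crosses(pair, q) for q in accepted):
            continue
        accepted.append(pair)
        used_cols.update(pair)
    if not accepted:
        logger.warning(
            "empty consensus structure: no pair reached threshold %.2f", threshold
        )
    return ConsensusStructure(frozenset(accepted), threshold)


class Role(str, Enum):
    STEM = "stem"
    LOOP = "loop"


@dataclass(frozen=True)
class PartitionMask:
    """Per-column stem/loop assignment with pair-partner indices.

    ``partner[i]`` is the paired column for stem columns and -1 for loops.
    """

    roles: tuple[Role, ...]
    partner: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "roles", tuple(self.roles))
        object.__setattr__(self, "partner", tuple(int(p) for p in self.partner))
        if len(self.roles) != len(self.partner):
            raise ValueError("roles and partner arrays differ in length")
        for i, (role, p) in enumerate(zip(self.roles, self.partner)):
            if role is Role.STEM:
                if not (0 <= p < len(self.roles)) or p == i:
                    raise ValueError(f"stem column {i} has invalid partner {p}")
                if self.partner[p] != i or self.roles[p] is not Role.STEM:
                    raise ValueError(f"partner relation not symmetric at column {i}")
            elif p != -1:
                raise ValueError(f"loop column {i} has partner {p}")

    @property
    def columns(self) -> int:
        return len(self.roles)

    @property
    def stem_columns(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r is Role.STEM]

    @property
    def loop_columns(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r is Role.LOOP]

    @property
    def stem_pairs(self) -> list[tuple[int, int]]:
        """Consensus pairs (i, j) with i < j."""
        return [
            (i, p) for i, p in enumerate(self.partner) if p != -1 and i < p
        ]

    @property
    def n_stem_pairs(self) -> int:
        return len(self.stem_pairs)

    @property
    def n_loop(self) -> int:
        return len(self.loop_columns)

    def to_tsv(self) -> str:
        """Export as TSV (1-based columns in the report, per convention)."""
        lines = ["column\trole\tpartner"]
        for i, (role, p) in enumerate(zip(self.roles, self.partner)):
            lines.append(f"{i + 1}\t{role.value}\t{p + 1 if p != -1 else '.'}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PartitionMask":
        roles, partner = [], []
        for ln in text.strip().splitlines()[1:]:
            _col, role, p = ln.split("\t")
            roles.append(Role(role))
            partner.append(int(p) - 1 if p != "." else -1)
        return cls(tuple(roles), tuple(partner))


def partition_alignment(aln: Alignment, cons: ConsensusStructure) -> PartitionMask:
    """Assign every column STEM (in a consensus pair) or LOOP (otherwise)."""
    n = aln.columns
    roles = [Role.LOOP] * n
    partner = [-1] * n
    for i, j in cons.pairs:
        if j >= n:
            raise ValueError(f"consensus pair ({i},{j}) outside alignment of {n} columns")
        roles[i] = roles[j] = Role.STEM
        partner[i], partner[j] = j, i
    return PartitionMask(tuple(roles), tuple(partner))
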