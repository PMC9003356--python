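"""Sister-species-pair screening via K2P neighbor-joining with bootstrap.

A genus-level alignment is screened in three steps mirroring standard
barcoding practice: (1) pairwise K2P distances with complete deletion of
gapped columns, (2) a neighbor-joining tree whose edges get bootstrap
support from column resampling, (3) screening — a species is successfully
identified iff its individuals form a clade with support above 50 %, the
genus passes iff at least half its (multi-individual) species are
identified, and a sister species pair (SSP) is a pair of identified species
whose clades are adjacent across a single internal edge with support above
50 %.  Support thresholds are strict inequalities.

Neighbor joining is implemented directly so that tie-breaking is
deterministic (lowest node-creation index) and additive matrices are
recovered exactly; library NJ implementations serve as independent oracles
in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .distance import DistanceResult, k2p_distance
from .errors import SaturationError
from .models import NT_STATES, is_transition
from .seqstruct import Alignment

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledTree",
    "SSPRecord",
    "ScreenResult",
    "distance_matrix_k2p",
    "nj_tree",
    "bootstrap_support",
    "screen_genus",
]

_NT_CODE = {nt: k for k, nt in enumerate(NT_STATES)}
_PURINE = {0, 2}  # A, G


@dataclass
class LabeledTree:
    """An unrooted tree with labeled leaves, branch lengths, and edge supports.

    ``adj`` is a symmetric adjacency map node -> {neighbor: branch length};
    ``leaf_name`` labels the leaf nodes.  ``supports`` maps normalised splits
    (the frozenset of leaf names on the side not containing the reference
    leaf) to bootstrap percentages.
    """

    adj: dict[int, dict[int, float]]
    leaf_name: dict[int, str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_name.values())

    def _ref_leaf(self) -> str:
        return min(self.leaf_name.values())

    def normalize_split(self, side: frozenset) -> frozenset:
        all_leaves = frozenset(self.leaf_name.values())
        return side if self._ref_leaf() not in side else all_leaves - side

    def splits(self) -> dict[frozenset, tuple[int, int]]:
        """Normalised non-trivial splits -> defining edge (u, v)."""
        out: dict[frozenset, tuple[int, int]] = {}
        n_leaves = len(self.leaf_name)
        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    side = frozenset(self._leaves_beyond(v, u))
                    if 2 <= len(side) <= n_leaves - 2:
                        out[self.normalize_split(side)] = (u, v)
        return out

    def _leaves_beyond(self, start: int, blocked: int) -> list[str]:
        seen, stack, names = {blocked, start}, [start], []
        while stack:
            node = stack.pop()
            if node in self.leaf_name:
                names.append(self.leaf_name[node])
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return names

    def leaf_distance(self, a: str, b: str) -> float:
        """Path length between two leaves."""
        ids = {v: k for k, v in self.leaf_name.items()}
        start, goal = ids[a], ids[b]
        seen = {start}
        stack = [(start, 0.0)]
        while stack:
            node, d = stack.pop()
            if node == goal:
                return d
            for nb, length in self.adj[node].items():
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, d + length))
        raise ValueError("tree is disconnected")

    def support_of(self, side: frozenset) -> Optional[float]:
        """Bootstrap support of a split given as a set of leaf names."""
        key = self.normalize_split(frozenset(side))
        if key in self.supports:
            return self.supports[key]
        return 100.0 if not self.supports and key in self.splits() else None

    def newick(self) -> str:
        """Newick string with supports as internal-node labels."""
        root = next(n for n in self.adj if n not in self.leaf_name)
        split_support = {}
        if self.supports:
            for side, (u, v) in self.splits().items():
                split_support[(u, v)] = self.supports.get(side)

        def fmt(node: int, parent: int, brlen: float | None) -> str:
            if node in self.leaf_name:
                core = self.leaf_name[node]
            else:
                parts = [
                    fmt(nb, node, self.adj[node][nb])
                    for nb in sorted(self.adj[node])
                    if nb != parent
                ]
                sup = split_support.get(tuple(sorted((node, parent)))) if parent != -1 else None
                label = "" if sup is None else f"{sup:g}"
                core = f"({','.join(parts)}){label}"
            return core if brlen is None else f"{core}:{brlen:.6g}"

        return fmt(root, -1, None) + ";"


@dataclass
class SSPRecord:
    """A validated sister species pair on the genus tree."""

    species_a: str
    species_b: str
    support: float
    gd_dna: Optional[DistanceResult] = None
    gd_rna: Optional[DistanceResult] = None


@dataclass
class ScreenResult:
    resolution: float
    identified: list[str]
    ssps: list[SSPRecord]
    assessed_species: list[str]
    excluded_single_individual: list[str]

    @property
    def passes(self) -> bool:
        """Genus-level gate: species resolution of at least 50 %."""
        return self.resolution >= 0.5


def _encode(aln: Alignment) -> np.ndarray:
    E = np.full((len(aln), aln.columns), -1, dtype=np.int8)
    for r, rec in enumerate(aln.records):
        for c, nt in enumerate(rec.sequence):
            E[r, c] = _NT_CODE.get(nt, -1)
    return E


def _k2p_matrix_encoded(E: np.ndarray) -> np.ndarray:
    """K2P matrix from an encoded alignment, global complete deletion."""
    usable = np.all(E >= 0, axis=0)
    if not usable.any():
        raise ValueError("complete deletion left no usable columns")
    E = E[:, usable]
    n, L = E.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = E[i] != E[j]
            both_purine = np.isin(E[i], list(_PURINE)) & np.isin(E[j], list(_PURINE))
            both_pyrim = ~np.isin(E[i], list(_PURINE)) & ~np.isin(E[j], list(_PURINE))
            ts = diff & (both_purine | both_pyrim)
            P = ts.sum() / L
            Q = (diff.sum() - ts.sum()) / L
            try:
                D[i, j] = D[j, i] = k2p_distance(P, Q)
            except SaturationError:
                D[i, j] = D[j, i] = np.inf
                logger.warning("K2P saturation between rows %d and %d", i, j)
    return D


def distance_matrix_k2p(aln: Alignment) -> np.ndarray:
    """Pairwise K2P distances on columns gap-free across all records."""
    if len(aln) < 3:
        raise ValueError("need at least 3 records for a distance matrix")
    return _k2p_matrix_encoded(_encode(aln))


def nj_tree(D: np.ndarray, labels: Sequence[str]) -> LabeledTree:
    """Neighbor joining with deterministic lowest-index tie-breaking.

    On an additive matrix the generating topology and branch lengths are
    recovered exactly.  Negative branch-length estimates are clamped to 0.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.isfinite(D).all():
        raise ValueError("distance matrix contains non-finite entries (saturation?)")
    if len(labels) != n or len(set(labels)) != n:
        raise ValueError("labels must be unique and match the matrix")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_name = {i: labels[i] for i in range(n)}
    active = list(range(n))
    next_id = n

    def connect(u: int, v: int, length: float):
        length = max(0.0, length)
        adj.setdefault(u, {})[v] = length
        adj.setdefault(v, {})[u] = length

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d(i, j) - R[i] - R[j]
                if q < best_q:  # strict: first (lowest-index) minimum wins
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d(i, j) + (R[i] - R[j]) / (2 * (r - 2))
        lj = d(i, j) - li
        u = next_id
        next_id += 1
        connect(u, i, li)
        connect(u, j, lj)
        for k in active:
            if k not in (i, j):
                dist[(min(u, k), max(u, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [k for k in active if k not in (i, j)] + [u]
    a, b, c = active
    u = next_id
    connect(u, a, 0.5 * (d(a, b) + d(a, c) - d(b, c)))
    connect(u, b, 0.5 * (d(a, b) + d(b, c) - d(a, c)))
    connect(u, c, 0.5 * (d(a, c) + d(b, c) - d(a, b)))
    return LabeledTree(adj=adj, leaf_name=leaf_name)


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int | None = None,
    max_redraws: int = 100,
) -> LabeledTree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement; each replicate's K2P/NJ tree
    contributes to the support (percentage of replicates containing the same
    bipartition) of the original tree's internal edges.  Degenerate
    replicates (complete deletion empty, or saturated distances) are
    redrawn, up to ``max_redraws`` times each.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    E = _encode(aln)
    labels = [r.id for r in aln.records]
    tree = nj_tree(_k2p_matrix_encoded(E), labels)
    target_splits = list(tree.splits().keys())
    hits = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        for _attempt in range(max_redraws):
            cols = rng.integers(0, aln.columns, aln.columns)
            try:
                Db = _k2p_matrix_encoded(E[:, cols])
                if not np.isfinite(Db).all():
                    continue
                rep_tree = nj_tree(Db, labels)
            except ValueError:
                continue
            rep_splits = set(rep_tree.splits().keys())
            for s in target_splits:
                if s in rep_splits:
                    hits[s] += 1
            break
        else:
            raise RuntimeError("bootstrap replicate could not be drawn (degenerate data)")
    tree.supports = {s: 100.0 * hits[s] / replicates for s in target_splits}
    return tree


def screen_genus(tree: LabeledTree, species_map: Mapping[str, Sequence[str]]) -> ScreenResult:
    """Apply the species-resolution / monophyly / sisterhood screening rules.

    ``species_map`` maps species name -> individual (leaf) ids.  Species with
    a single individual are excluded from the monophyly assessment (logged).
    Sisterhood of two identified species means their clades are adjacent
    across one internal edge of the unrooted tree, i.e. the union of their
    leaves is itself a split side (or the whole leaf set when only the two
    species remain), with that edge's support above 50.
    """
    if len(species_map) < 2:
        raise ValueError("need at least 2 species to screen")
    all_leaves = frozenset(tree.leaf_name.values())
    assessed: dict[str, frozenset] = {}
    singles: list[str] = []
    for sp, ids in sorted(species_map.items()):
        ids = frozenset(ids) & all_leaves
        if len(ids) >= 2:
            assessed[sp] = ids
        else:
            singles.append(sp)
            logger.info("species %s has < 2 individuals; excluded from monophyly", sp)
    identified: list[str] = []
    for sp, ids in assessed.items():
        sup = tree.support_of(ids)
        if sup is not None and sup > 50.0:
            identified.append(sp)
    resolution = len(identified) / len(assessed) if assessed else 0.0
    ssps: list[SSPRecord] = []
    for ai, sp_a in enumerate(identified):
        for sp_b in identified[ai + 1:]:
            union = assessed[sp_a] | assessed[sp_b]
            if union == all_leaves:
                # only these two clades remain: the edge joining them is the
                # same edge that defines each species' monophyly
                sup = tree.support_of(assessed[sp_a])
            else:
                sup = tree.support_of(union)
            if sup is not None and sup > 50.0:
                ssps.append(SSPRecord(sp_a, sp_b, sup))
    if len(identified) == 3 and len(ssps) == 3:
        # three clades hanging off one node: the unrooted topology alone
        # cannot name the sister pair (every union is a split through its
        # complement), so branch lengths break the tie — the pair with the
        # shortest mean inter-clade path is the sisters, the third species
        # the outgroup
        def mean_dist(rec: SSPRecord) -> float:
            pairs = [
                tree.leaf_distance(x, y)
                for x in assessed[rec.species_a]
                for y in assessed[rec.species_b]
            ]
            return sum(pairs) / len(pairs)

        ssps = [min(ssps, key=lambda r: (mean_dist(r), r.species_a, r.species_b))]
    return ScreenResult(
        resolution=resolution,
        identified=identified,
        ssps=ssps,
        assessed_species=sorted(assessed),
        excluded_single_individual=singles,
    )
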