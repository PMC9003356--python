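import numpy as np
import pytest

from its2dist import Alignment, SeqStructRecord, build_model
from its2dist.distance import pair_log_likelihood
from its2dist.models import free_param_names


def random_pattern_counts(rng, name, space, n_sites=500):
    """A random model of the named family plus pattern counts simulated from
    it at a random divergence — identifiable data for optimiser oracles."""
    params = {p: float(rng.uniform(0.3, 3.0)) for p in free_param_names(name)}
    n = 7 if space == 7 else 16
    pi = rng.dirichlet(np.full(n, 8.0))
    model = build_model(name, params, pi)
    t_true = float(rng.uniform(0.05, 1.0))
    P = model.transition_matrix(t_true)
    joint = (model.pi[:, None] * P).ravel()
    draws = rng.multinomial(n_sites, joint / joint.sum())
    return model, draws.reshape(n, n)


def random_additive_tree(rng, n_taxa):
    """A random binary tree and its exact leaf-to-leaf distance matrix.

    Returns (matrix, branch-length map, set of normalised non-trivial splits
    over labels t0..t{n-1}) — the oracle for neighbor-joining exactness.
    """
    lengths = {}
    parent = {}
    nodes = list(range(n_taxa))
    nxt = n_taxa
    while len(nodes) > 1:
        i = nodes.pop(int(rng.integers(len(nodes))))
        j = nodes.pop(int(rng.integers(len(nodes))))
        for child in (i, j):
            parent[child] = nxt
            lengths[child] = float(rng.uniform(0.1, 2.0))
        nodes.append(nxt)
        nxt += 1
    root = nodes[0]

    def path_to_root(v):
        out = {}
        d = 0.0
        while v != root:
            d += lengths[v]
            v = parent[v]
            out[v] = d
        return out

    D = np.zeros((n_taxa, n_taxa))
    anc = [path_to_root(i) for i in range(n_taxa)]
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            mrca_d = min(anc[i][v] + anc[j][v] for v in anc[i] if v in anc[j])
            D[i, j] = D[j, i] = mrca_d
    splits = set()
    for v in parent:  # edge v -- parent[v]
        below = {v} if v < n_taxa else set()
        stack = [v]
        while stack:
            u = stack.pop()
            if u < n_taxa:
                below.add(u)
            stack.extend(c for c in parent if parent[c] == u)
        if 2 <= len(below) <= n_taxa - 2:
            side = frozenset(f"t{k}" for k in below)
            if "t0" in side:
                side = frozenset(f"t{k}" for k in range(n_taxa)) - side
            splits.add(side)
    return D, lengths, splits


def grid_argmax(C, model, t_max=5.0, step=1e-4):
    """Dense-grid brute-force ML distance (the independent oracle).

    Vectorised over the grid via the model's spectral decomposition.
    """
    w, right, left = model._decompose()
    ts = np.arange(0.0, t_max + step / 2, step)
    # P(t) for all grid points: (T, n, n)
    expwt = np.exp(np.outer(ts, w))
    Pt = np.einsum("ik,tk,kj->tij", right, expwt, left)
    M = np.clip(model.pi[None, :, None] * Pt, 1e-300, None)
    lls = np.einsum("ij,tij->t", C, np.log(M))
    return float(ts[np.argmax(lls)])


@pytest.fixture
def hairpin_records() -> list[SeqStructRecord]:
    """Four aligned records sharing the ((..)) hairpin."""
    return [
        SeqStructRecord("r1", "GGAACC", "((..))"),
        SeqStructRecord("r2", "GGAACC", "((..))"),
        SeqStructRecord("r3", "GCAAGC", "((..))"),
        SeqStructRecord("r4", "GGUACC", "((..))"),
    ]


@pytest.fixture
def hairpin_alignment(hairpin_records) -> Alignment:
    return Alignment(tuple(hairpin_records))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
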