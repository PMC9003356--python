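"""Reversible substitution models on 4, 7, and 16 states.

Loop (unpaired) columns evolve under standard nucleotide models (JC69, K2P,
HKY85, REV); stem (paired) columns evolve under paired-site models whose
states are dinucleotides — either all 16 ordered dinucleotides, or the six
pairing states {AU, GU, GC, UA, UG, CG} plus a lumped mismatch state MM
(7-state family).  Every model is a general time-reversible Markov generator
Q_ij = s_ij * pi_j with symmetric exchangeabilities s_ij, normalised so one
substitution event is expected per site per unit time.

The default paired presets allow only single-nucleotide moves: a full
compensatory change (AU -> GC) is a two-step process through a wobble
intermediate (AU -> GU -> GC).  Preset constraint sets live in
``data/model_presets.yaml`` and can be edited without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import combinations
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "NT_STATES",
    "PAIR7_STATES",
    "PAIR16_STATES",
    "PAIRING_STATES",
    "MISMATCH_STATES",
    "ModelParams",
    "SubstModel",
    "build_model",
    "transition_matrix",
    "pair_state_of",
    "independent_pair_model",
    "free_param_names",
    "n_rate_params",
    "n_freq_params",
    "empirical_frequencies",
    "MODEL_NAMES",
]

NT_STATES: tuple[str, ...] = ("A", "C", "G", "U")
PAIR7_STATES: tuple[str, ...] = ("AU", "GU", "GC", "UA", "UG", "CG", "MM")
PAIR16_STATES: tuple[str, ...] = tuple(x + y for x in NT_STATES for y in NT_STATES)
PAIRING_STATES: frozenset[str] = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})
MISMATCH_STATES: tuple[str, ...] = tuple(
    s for s in PAIR16_STATES if s not in PAIRING_STATES
)
_PURINES = {"A", "G"}
_TRANSITION_PAIRS = {frozenset({"A", "G"}), frozenset({"C", "U"})}

MODEL_NAMES = ("JC69", "K2P", "HKY85", "REV", "RNA7A", "RNA7G", "RNA16", "RNA16REV")

_FREQ_FLOOR = 1e-6


def _load_presets() -> dict:
    with resources.files("its2dist.data").joinpath("model_presets.yaml").open() as fh:
        return yaml.safe_load(fh)


_PRESETS = _load_presets()


def is_transition(x: str, y: str) -> bool:
    return frozenset({x, y}) in _TRANSITION_PAIRS


def pair_state_of(x: str, y: str, space: int) -> Optional[int]:
    """Index of the pair state of nucleotides (x, y) in the 7- or 16-space.

    Returns None ('unscorable') for gaps or ambiguity codes; the caller
    decides the deletion policy.
    """
    if x not in NT_STATES or y not in NT_STATES:
        return None
    di = x + y
    if space == 16:
        return PAIR16_STATES.index(di)
    if space == 7:
        return PAIR7_STATES.index(di) if di in PAIRING_STATES else 6
    raise ValueError(f"pair state space must be 7 or 16, got {space}")


def _edge_name(a: str, b: str, states: Sequence[str]) -> str:
    i, j = sorted((states.index(a), states.index(b)))
    return f"{states[i]}:{states[j]}"


def _single_sub_edges(states: Sequence[str]) -> list[tuple[str, str]]:
    """Unordered dinucleotide pairs differing at exactly one position."""
    out = []
    for a, b in combinations(states, 2):
        if (a[0] == b[0]) != (a[1] == b[1]):  # exactly one position differs
            out.append((a, b))
    return out


def free_param_names(name: str) -> list[str]:
    """Ordered free rate-parameter names of a model (one edge held at 1)."""
    if name == "JC69":
        return []
    if name in ("K2P", "HKY85"):
        return ["kappa"]
    if name == "REV":
        return ["A:C", "A:G", "A:U", "C:G", "C:U"]  # G:U fixed at 1
    if name == "RNA7G":
        return ["alpha"]  # beta fixed at 1
    if name == "RNA7A":
        edges = [f"{a}:{b}" for a, b in combinations(PAIR7_STATES, 2)]
        return edges[:-1]  # last edge fixed at 1
    if name == "RNA16":
        edges = [_edge_name(a, b, PAIR16_STATES) for a, b in _single_sub_edges(PAIR16_STATES)]
        return edges[:-1]
    if name == "RNA16REV":
        edges = [f"{a}:{b}" for a, b in combinations(PAIR16_STATES, 2)]
        return edges[:-1]
    raise ValueError(f"unknown model {name!r}")


def n_rate_params(name: str) -> int:
    return len(free_param_names(name))


def n_freq_params(name: str) -> int:
    """Free stationary-frequency parameters when frequencies are estimated."""
    if name in ("JC69", "K2P"):
        return 0
    if name in ("HKY85", "REV"):
        return 3
    if name in ("RNA7A", "RNA7G"):
        return 6
    if name in ("RNA16", "RNA16REV"):
        return 15
    raise ValueError(f"unknown model {name!r}")


@dataclass(frozen=True)
class ModelParams:
    """Named free-parameter values of a model; ``k`` is the free dimension."""

    values: Mapping[str, float]
    k: int

    def __post_init__(self):
        for key, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative rate parameter {key}={v}")

    @classmethod
    def for_model(cls, name: str, values: Mapping[str, float] | None = None) -> "ModelParams":
        names = free_param_names(name)
        vals = {p: 1.0 for p in names}
        if values:
            unknown = set(values) - set(names)
            if unknown:
                raise ValueError(f"unknown parameters for {name}: {sorted(unknown)}")
            vals.update(values)
        return cls(dict(vals), len(names))


@dataclass(eq=False)
class SubstModel:
    """A reversible substitution model: states, frequencies, generator."""

    name: str
    states: tuple[str, ...]
    pi: np.ndarray
    s: np.ndarray  # symmetric exchangeabilities, zero diagonal
    Q: np.ndarray = field(init=False)
    params: ModelParams | None = None
    _spectral: tuple | None = field(default=None, init=False, repr=False)

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        n = len(self.states)
        if self.pi.shape != (n,):
            raise ValueError(f"pi has wrong length for {n}-state model")
        if np.any(self.pi <= 0) or not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must be positive and sum to 1")
        if self.s.shape != (n, n) or not np.allclose(self.s, self.s.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(self.s < 0):
            raise ValueError("exchangeabilities must be nonnegative")
        Q = self.s * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.dot(self.pi, np.diag(Q))
        if rate <= 0:
            raise ValueError("degenerate model: zero total rate")
        self.Q = Q / rate

    @property
    def n_states(self) -> int:
        return len(self.states)

    def _decompose(self):
        # Symmetrise B = D^{1/2} Q D^{-1/2}; reversibility gives a real spectrum.
        if self._spectral is None:
            d = np.sqrt(self.pi)
            B = (self.Q * d[:, None]) / d[None, :]
            B = 0.5 * (B + B.T)
            w, V = np.linalg.eigh(B)
            left = V.T * d[None, :]      # V^T D^{1/2}
            right = V / d[:, None]       # D^{-1/2} V
            self._spectral = (w, right, left)
        return self._spectral

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped into [0, 1]."""
        if t < 0:
            raise ValueError(f"time must be nonnegative, got {t}")
        try:
            w, right, left = self._decompose()
            P = (right * np.exp(w * t)[None, :]) @ left
        except np.linalg.LinAlgError:  # pragma: no cover - fallback path
            from scipy.linalg import expm

            P = expm(self.Q * t)
        P = np.clip(P, 0.0, 1.0)
        return P / P.sum(axis=1, keepdims=True)


def transition_matrix(m: SubstModel, t: float) -> np.ndarray:
    return m.transition_matrix(t)


def empirical_frequencies(counts: np.ndarray, floor: float = _FREQ_FLOOR) -> np.ndarray:
    """Normalised frequencies with a pseudo-frequency floor for absent states."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    freqs = counts / total if total > 0 else np.full(len(counts), 1.0 / len(counts))
    freqs = np.maximum(freqs, floor)
    return freqs / freqs.sum()


@lru_cache(maxsize=None)
def rate_matrix_builder(name: str) -> Callable[[np.ndarray], np.ndarray]:
    """A fast vectorised builder: free-rate vector -> exchangeability matrix.

    The vector follows :func:`free_param_names` order; the held-out edge is 1.
    Used by the optimiser, which evaluates thousands of candidate matrices.
    """
    if name == "JC69":
        base4 = np.ones((4, 4)) - np.eye(4)
        return lambda v: base4.copy()
    if name in ("K2P", "HKY85"):
        ts = np.zeros((4, 4), dtype=bool)
        for i, j in combinations(range(4), 2):
            if is_transition(NT_STATES[i], NT_STATES[j]):
                ts[i, j] = ts[j, i] = True
        tv = ~ts & ~np.eye(4, dtype=bool)

        def build_kappa(v: np.ndarray) -> np.ndarray:
            s = np.zeros((4, 4))
            s[tv] = 1.0
            s[ts] = v[0]
            return s

        return build_kappa
    if name == "RNA7G":
        preset = _PRESETS["RNA7G"]
        st = PAIR7_STATES
        a_idx = np.array([[st.index(a), st.index(b)] for a, b in preset["alpha_edges"]])
        b_idx = np.array([[st.index(a), st.index(b)] for a, b in preset["beta_edges"]])

        def build_7g(v: np.ndarray) -> np.ndarray:
            s = np.zeros((7, 7))
            s[a_idx[:, 0], a_idx[:, 1]] = v[0]
            s[b_idx[:, 0], b_idx[:, 1]] = 1.0
            return s + s.T

        return build_7g
    # general reversible families: free edges in name order, last edge fixed
    if name == "REV":
        states: tuple[str, ...] = NT_STATES
        edges = list(combinations(range(4), 2))
    elif name == "RNA7A":
        states = PAIR7_STATES
        edges = [(states.index(a), states.index(b)) for a, b in combinations(states, 2)]
    elif name == "RNA16":
        states = PAIR16_STATES
        edges = [(states.index(a), states.index(b)) for a, b in _single_sub_edges(states)]
    elif name == "RNA16REV":
        states = PAIR16_STATES
        edges = [(states.index(a), states.index(b)) for a, b in combinations(states, 2)]
    else:
        raise ValueError(f"unknown model {name!r}")
    n = len(states)
    rows = np.array([e[0] for e in edges])
    cols = np.array([e[1] for e in edges])

    def build_general(v: np.ndarray) -> np.ndarray:
        s = np.zeros((n, n))
        s[rows, cols] = np.append(v, 1.0)
        return s + s.T

    return build_general


def _nt_exchangeabilities(name: str, params: ModelParams) -> np.ndarray:
    n = 4
    s = np.zeros((n, n))
    if name == "JC69":
        s[:] = 1.0
    elif name in ("K2P", "HKY85"):
        kappa = params.values["kappa"]
        for i, j in combinations(range(n), 2):
            s[i, j] = kappa if is_transition(NT_STATES[i], NT_STATES[j]) else 1.0
        s = s + s.T
    elif name == "REV":
        vals = dict(params.values)
        vals.setdefault("G:U", 1.0)
        for i, j in combinations(range(n), 2):
            s[i, j] = vals[f"{NT_STATES[i]}:{NT_STATES[j]}"]
        s = s + s.T
    else:  # pragma: no cover
        raise ValueError(name)
    np.fill_diagonal(s, 0.0)
    return s


def _pair_exchangeabilities(name: str, params: ModelParams) -> tuple[np.ndarray, tuple[str, ...]]:
    if name in ("RNA7A", "RNA7G"):
        states = PAIR7_STATES
    else:
        states = PAIR16_STATES
    n = len(states)
    s = np.zeros((n, n))
    if name == "RNA7G":
        preset = _PRESETS["RNA7G"]
        alpha = params.values["alpha"]
        beta = 1.0
        for a, b in preset["alpha_edges"]:
            i, j = states.index(a), states.index(b)
            s[i, j] = s[j, i] = alpha
        for a, b in preset["beta_edges"]:
            i, j = states.index(a), states.index(b)
            s[i, j] = s[j, i] = beta
    elif name == "RNA7A":
        vals = dict(params.values)
        edges = [f"{a}:{b}" for a, b in combinations(states, 2)]
        vals.setdefault(edges[-1], 1.0)
        for a, b in combinations(states, 2):
            i, j = states.index(a), states.index(b)
            s[i, j] = s[j, i] = vals[f"{a}:{b}"]
    elif name == "RNA16":
        vals = dict(params.values)
        edges = [_edge_name(a, b, states) for a, b in _single_sub_edges(states)]
        vals.setdefault(edges[-1], 1.0)
        for a, b in _single_sub_edges(states):
            i, j = states.index(a), states.index(b)
            s[i, j] = s[j, i] = vals[_edge_name(a, b, states)]
    elif name == "RNA16REV":
        vals = dict(params.values)
        edges = [f"{a}:{b}" for a, b in combinations(states, 2)]
        vals.setdefault(edges[-1], 1.0)
        for a, b in combinations(states, 2):
            i, j = states.index(a), states.index(b)
            s[i, j] = s[j, i] = vals[f"{a}:{b}"]
    else:  # pragma: no cover
        raise ValueError(name)
    return s, states


def build_model(
    name: str,
    params: ModelParams | Mapping[str, float] | None = None,
    pi: Sequence[float] | np.ndarray | None = None,
) -> SubstModel:
    """Construct a named substitution model.

    ``params`` supplies the free rate parameters (missing ones default to 1);
    ``pi`` the stationary frequencies.  JC69 and K2P force uniform
    frequencies.  For the default paired presets (RNA7G, RNA16) the
    exchangeability between states differing at both nucleotide positions is
    structurally zero.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    if not isinstance(params, ModelParams):
        params = ModelParams.for_model(name, params)
    if name in ("JC69", "K2P"):
        if pi is not None and not np.allclose(pi, 0.25):
            raise ValueError(f"{name} requires uniform frequencies")
        pi_arr = np.full(4, 0.25)
        s = _nt_exchangeabilities(name, params)
        states: tuple[str, ...] = NT_STATES
    elif name in ("HKY85", "REV"):
        pi_arr = np.full(4, 0.25) if pi is None else np.asarray(pi, dtype=float)
        s = _nt_exchangeabilities(name, params)
        states = NT_STATES
    else:
        s, states = _pair_exchangeabilities(name, params)
        pi_arr = (
            np.full(len(states), 1.0 / len(states))
            if pi is None
            else np.asarray(pi, dtype=float)
        )
    return SubstModel(name=name, states=states, pi=pi_arr, s=s, params=params)


def independent_pair_model(m4: SubstModel, name: str = "IND16") -> SubstModel:
    """Lift a 4-state model to 16 dinucleotide states with independent positions.

    The generator is the Kronecker sum Q4 (+) Q4 and the stationary
    distribution the outer product of the nucleotide frequencies, then
    re-normalised to one event per pair-site per unit time.  All moves are
    single-nucleotide, and the two positions evolve independently — the
    16-state model under which paired-site and independent-site likelihoods
    coincide.
    """
    if m4.n_states != 4:
        raise ValueError("independent_pair_model needs a 4-state model")
    eye = np.eye(4)
    Q16 = np.kron(m4.Q, eye) + np.kron(eye, m4.Q)
    pi16 = np.outer(m4.pi, m4.pi).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        s16 = np.where(pi16[None, :] > 0, Q16 / pi16[None, :], 0.0)
    np.fill_diagonal(s16, 0.0)
    s16 = 0.5 * (s16 + s16.T)
    model = SubstModel(name=name, states=PAIR16_STATES, pi=pi16, s=s16)
    return model
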