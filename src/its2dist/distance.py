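"""Pairwise genetic distances under DNA and structure-partitioned RNA models.

GD_DNA treats every usable nucleotide column as an independent site under a
single 4-state model.  GD_RNA partitions the alignment by the consensus
structure: loop columns evolve under a nucleotide model with branch length
t_loop, stem pair-columns under a paired-site model with branch length
t_stem (in expected pair-model events per pair-site).  The mixed distance is
reported per site of the partitioned matrix, where a stem pair-column is a
single (two-nucleotide) site:

    GD_RNA = (n_loop * t_loop + n_stempairs * t_stem * c / 2) / (n_loop + n_stempairs),

with c the expected number of nucleotide changes per pair-model event (c = 1
for the single-substitution-only presets), so t_stem * c / 2 is the expected
nucleotide changes per stem *position*.  Weighting each coupled pair once is
the paired-site view of the data: a full compensatory change contributes one
substitution to one pair-site, where the independent-site GD_DNA counts two
changes at two sites.  When stems and loops evolve at the same
per-position rate the two conventions coincide (GD_RNA = GD_DNA in
expectation); when stems evolve faster, GD_RNA falls below GD_DNA — the
deviation the GD-ratio analysis quantifies.

Gaps and ambiguities are handled by complete deletion: a loop column is
dropped if either sequence is not a plain nucleotide there, and a stem
pair-column is dropped if any of its four nucleotides is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import RnaModelNotApplicableError, SaturationError, UndefinedRatioError
from .models import (
    NT_STATES,
    PAIR7_STATES,
    PAIR16_STATES,
    ModelParams,
    SubstModel,
    build_model,
    empirical_frequencies,
    free_param_names,
    pair_state_of,
    rate_matrix_builder,
)
from .seqstruct import Alignment, PartitionMask

__all__ = [
    "SitePatternCounts",
    "DistanceResult",
    "count_patterns",
    "p_distance",
    "ml_distance_dna",
    "ml_distance_mixed",
    "gd_ratio",
    "k2p_distance",
    "jc_distance",
    "pair_log_likelihood",
    "fit_model_to_counts",
    "changes_per_event",
    "DISTANCE_CAP",
]

DISTANCE_CAP = 10.0
_MULTISTART_T = (0.01, 0.1, 1.0)


@dataclass(frozen=True)
class SitePatternCounts:
    """Ordered site-pattern counts between two aligned records.

    ``loop_counts``: 4x4 nucleotide pair counts over loop columns.
    ``stem_counts``: SxS pair-state pattern counts over stem pair-columns in
    the chosen state space (7 or 16).
    ``nt_counts_all``: 4x4 counts over all usable nucleotide columns (stem
    columns unfolded to single sites) — the GD_DNA data.
    ``stem_nt_diff``: number of differing nucleotide positions within usable
    stem pair-columns (for p-distances and raw rates).
    """

    loop_counts: np.ndarray
    stem_counts: np.ndarray
    space: int
    nt_counts_all: np.ndarray
    stem_nt_diff: int
    n_loop: int
    n_stempairs: int

    def __post_init__(self):
        if self.loop_counts.min() < 0 or self.stem_counts.min() < 0:
            raise ValueError("negative pattern counts")
        if int(self.loop_counts.sum()) != self.n_loop:
            raise ValueError("loop counts do not total n_loop")
        if int(self.stem_counts.sum()) != self.n_stempairs:
            raise ValueError("stem counts do not total n_stempairs")

    @property
    def n_nucleotide_sites(self) -> int:
        """Usable nucleotide positions (pair-columns contribute 2)."""
        return self.n_loop + 2 * self.n_stempairs

    @property
    def n_mm_observations(self) -> int:
        """Sequence-site observations in the lumped MM state (7-space only)."""
        if self.space != 7:
            return 0
        mm = len(PAIR7_STATES) - 1
        return int(self.stem_counts[mm, :].sum() + self.stem_counts[:, mm].sum())


@dataclass(frozen=True)
class DistanceResult:
    """A maximum-likelihood genetic distance with its likelihood and model."""

    gd: float
    lnl: float
    model: str
    converged: bool
    t_loop: Optional[float] = None
    t_stem: Optional[float] = None
    lnl_loop: Optional[float] = None
    lnl_stem: Optional[float] = None
    params: Optional[dict] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.gd < 0:
            raise ValueError("genetic distance cannot be negative")


def count_patterns(aln2: Alignment, mask: PartitionMask, space: int = 7) -> SitePatternCounts:
    """Tabulate ordered site patterns of a 2-record alignment under a mask."""
    if len(aln2) != 2:
        raise ValueError("count_patterns needs exactly 2 records")
    if mask.columns != aln2.columns:
        raise ValueError(
            f"mask has {mask.columns} columns but alignment has {aln2.columns}"
        )
    a, b = aln2[0].sequence, aln2[1].sequence
    nstates = 7 if space == 7 else 16
    loop = np.zeros((4, 4), dtype=int)
    stem = np.zeros((nstates, nstates), dtype=int)
    nt_all = np.zeros((4, 4), dtype=int)
    stem_nt_diff = 0
    nt_index = {nt: k for k, nt in enumerate(NT_STATES)}
    for col in mask.loop_columns:
        x, y = a[col], b[col]
        if x in nt_index and y in nt_index:
            loop[nt_index[x], nt_index[y]] += 1
            nt_all[nt_index[x], nt_index[y]] += 1
    for i, j in mask.stem_pairs:
        nts = (a[i], a[j], b[i], b[j])
        if not all(n in nt_index for n in nts):
            continue  # complete deletion of the whole pair-column
        sa = pair_state_of(a[i], a[j], space)
        sb = pair_state_of(b[i], b[j], space)
        stem[sa, sb] += 1
        stem_nt_diff += int(a[i] != b[i]) + int(a[j] != b[j])
        nt_all[nt_index[a[i]], nt_index[b[i]]] += 1
        nt_all[nt_index[a[j]], nt_index[b[j]]] += 1
    return SitePatternCounts(
        loop_counts=loop,
        stem_counts=stem,
        space=space,
        nt_counts_all=nt_all,
        stem_nt_diff=stem_nt_diff,
        n_loop=int(loop.sum()),
        n_stempairs=int(stem.sum()),
    )


def p_distance(counts: SitePatternCounts) -> float:
    """Observed fraction of differing nucleotide positions (stems count 2)."""
    total = counts.n_nucleotide_sites
    if total == 0:
        raise ValueError("no usable sites")
    loop_diff = int(counts.loop_counts.sum() - np.trace(counts.loop_counts))
    return (loop_diff + counts.stem_nt_diff) / total


def jc_distance(p: float) -> float:
    """Jukes-Cantor closed-form distance from a fraction of differing sites."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise SaturationError(f"JC distance undefined for p = {p}")
    return -0.75 * math.log(arg)


def k2p_distance(P: float, Q: float) -> float:
    """Kimura 2-parameter closed form from transition (P) and transversion (Q)
    difference fractions: d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        raise SaturationError(f"K2P distance undefined for P = {P}, Q = {Q}")
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def pair_log_likelihood(C: np.ndarray, model: SubstModel, t: float) -> float:
    """log L = sum_xy C_xy log(pi_x P_xy(t)) for ordered pattern counts C."""
    P = model.transition_matrix(t)
    M = np.clip(model.pi[:, None] * P, 1e-300, None)
    nz = C > 0
    return float(np.sum(C[nz] * np.log(M[nz])))


def _pooled_state_frequencies(C: np.ndarray) -> np.ndarray:
    return empirical_frequencies(C.sum(axis=0) + C.sum(axis=1))


def fit_model_to_counts(
    C: np.ndarray,
    name: str,
    pi: np.ndarray | None = None,
    init_params: Mapping[str, float] | None = None,
    estimate_params: bool = True,
    cap: float = DISTANCE_CAP,
    max_iter: int = 500,
) -> tuple[float, ModelParams, float, bool]:
    """Maximise the pairwise likelihood over t (and, optionally, the model's
    free rate parameters) for ordered pattern counts C.

    Frequencies are fixed: supplied, or pooled empirically from C (with the
    pseudo-frequency floor).  Returns (t_hat, params, lnL, converged); an
    estimate pinned at the cap with the likelihood still increasing is
    flagged converged=False (saturation).
    """
    if pi is None:
        pi = _pooled_state_frequencies(C)
    C = np.asarray(C)
    if C.sum() - np.trace(C) == 0:
        # diagonal-only counts: lnL(t) = sum_i C_ii log(pi_i P_ii(t)) is
        # maximised exactly at t = 0 since P_ii(t) <= 1
        uniform0 = name in ("JC69", "K2P")
        model0 = build_model(name, init_params, None if uniform0 else pi)
        return 0.0, ModelParams.for_model(name, init_params), pair_log_likelihood(
            C, model0, 0.0
        ), True
    pnames = free_param_names(name) if estimate_params else []
    init = {p: 1.0 for p in pnames}
    if init_params:
        init.update({k: v for k, v in init_params.items() if k in init})
    uniform = name in ("JC69", "K2P")

    if estimate_params and pnames:
        builder = rate_matrix_builder(name)
        template = build_model(name, None, None if uniform else pi)
        states, pi_used = template.states, template.pi

        def neg_lnl(theta: np.ndarray) -> float:
            try:
                m = SubstModel(name=name, states=states, pi=pi_used,
                               s=builder(theta[1:]))
                return -pair_log_likelihood(C, m, theta[0])
            except (ValueError, FloatingPointError):
                return 1e12
    else:
        fixed = build_model(name, init_params, None if uniform else pi)

        def neg_lnl(theta: np.ndarray) -> float:
            try:
                return -pair_log_likelihood(C, fixed, theta[0])
            except (ValueError, FloatingPointError):
                return 1e12

    bounds = [(0.0, cap)] + [(1e-6, 1e4)] * len(pnames)
    best = None
    # high-dimensional fits use a single start; t is the only multistart axis
    starts = _MULTISTART_T if len(pnames) <= 5 else (0.1,)
    for t0 in starts:
        x0 = np.array([t0] + [init[p] for p in pnames])
        res = minimize(
            neg_lnl,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    t_hat = float(best.x[0])
    vals = {p: float(best.x[1 + k]) for k, p in enumerate(pnames)}
    lnl = -float(best.fun)
    converged = True
    if t_hat >= 0.999 * cap:
        # saturation check: is the likelihood still increasing at the cap?
        theta_in = best.x.copy()
        theta_in[0] = 0.995 * cap
        if -neg_lnl(best.x) > -neg_lnl(theta_in):
            converged = False
            t_hat = cap
    params = ModelParams(vals, len(pnames)) if pnames else ModelParams({}, 0)
    return t_hat, params, lnl, converged


def ml_distance_dna(
    counts: SitePatternCounts,
    m: SubstModel | str = "K2P",
    estimate_params: bool = True,
    cap: float = DISTANCE_CAP,
) -> DistanceResult:
    """ML distance treating all usable columns as independent nucleotide sites.

    ``m`` may be a model name (frequencies pooled empirically where free) or a
    built :class:`SubstModel` whose frequencies are then held fixed.
    """
    name = m if isinstance(m, str) else m.name
    if name not in ("JC69", "K2P", "HKY85", "REV"):
        raise ValueError(f"{name} is not a 4-state model")
    C = counts.nt_counts_all
    if C.sum() == 0:
        raise ValueError("no usable sites")
    pi = None if isinstance(m, str) else m.pi
    init = None if isinstance(m, str) or m.params is None else m.params.values
    t_hat, params, lnl, converged = fit_model_to_counts(
        C, name, pi=pi, init_params=init, estimate_params=estimate_params, cap=cap
    )
    flags = () if converged else ("dna_saturated",)
    return DistanceResult(
        gd=t_hat, lnl=lnl, model=name, converged=converged,
        params=dict(params.values), flags=flags,
    )


def changes_per_event(model: SubstModel) -> float:
    """Expected nucleotide changes per pair-model substitution event.

    Rate-weighted Hamming distance of the model's moves; moves to or from the
    lumped MM state count as one change (the single-nucleotide routes).
    Equals 1 exactly for single-substitution-only presets.
    """
    if model.n_states == 4:
        return 1.0
    total, weighted = 0.0, 0.0
    for i, si in enumerate(model.states):
        for j, sj in enumerate(model.states):
            if i == j or model.Q[i, j] <= 0:
                continue
            if si == "MM" or sj == "MM":
                ham = 1
            else:
                ham = int(si[0] != sj[0]) + int(si[1] != sj[1])
            flux = model.pi[i] * model.Q[i, j]
            total += flux
            weighted += flux * ham
    return weighted / total if total > 0 else 1.0


def ml_distance_mixed(
    counts: SitePatternCounts,
    m_loop: SubstModel | str = "HKY85",
    m_stem: SubstModel | str = "RNA7G",
    estimate_params: bool = True,
    cap: float = DISTANCE_CAP,
    max_iter_stem: int = 500,
) -> DistanceResult:
    """Joint ML distance under a loop nucleotide model and a stem pair model.

    The two partitions have separate branch lengths and separate parameters,
    so the joint maximisation splits into two independent fits; the reported
    lnL is their sum.  Raises :class:`RnaModelNotApplicableError` when a
    partition has no usable sites (mirroring the screening step that removes
    such alignments).
    """
    if counts.n_loop == 0 or counts.n_stempairs == 0:
        raise RnaModelNotApplicableError(
            "RNA model not applicable: "
            f"n_loop={counts.n_loop}, n_stempairs={counts.n_stempairs}"
        )
    loop_name = m_loop if isinstance(m_loop, str) else m_loop.name
    stem_name = m_stem if isinstance(m_stem, str) else m_stem.name
    expected = 7 if stem_name in ("RNA7A", "RNA7G") else 16
    if counts.stem_counts.shape[0] != expected:
        raise ValueError(
            f"counts are in {counts.stem_counts.shape[0]}-state space but "
            f"{stem_name} needs {expected}"
        )
    t_loop, p_loop, lnl_loop, conv_loop = fit_model_to_counts(
        counts.loop_counts,
        loop_name,
        pi=None if isinstance(m_loop, str) else m_loop.pi,
        init_params=None if isinstance(m_loop, str) or m_loop.params is None else m_loop.params.values,
        estimate_params=estimate_params,
        cap=cap,
    )
    stem_pi = None if isinstance(m_stem, str) else m_stem.pi
    is_preset = stem_name in ("RNA7A", "RNA7G", "RNA16", "RNA16REV")
    if is_preset:
        t_stem, p_stem, lnl_stem, conv_stem = fit_model_to_counts(
            counts.stem_counts,
            stem_name,
            pi=stem_pi,
            init_params=None if isinstance(m_stem, str) or m_stem.params is None else m_stem.params.values,
            estimate_params=estimate_params,
            cap=cap,
            max_iter=max_iter_stem,
        )
        if estimate_params:
            fitted = build_model(
                stem_name,
                dict(p_stem.values),
                stem_pi if stem_pi is not None
                else _pooled_state_frequencies(counts.stem_counts),
            )
            c = changes_per_event(fitted)
        else:
            c = changes_per_event(
                m_stem if isinstance(m_stem, SubstModel) else build_model(stem_name)
            )
    else:
        # prebuilt custom pair model (e.g. an independent-position lift)
        t_stem, p_stem, lnl_stem, conv_stem = _fit_fixed_pair(
            counts.stem_counts, m_stem, cap
        )
        c = changes_per_event(m_stem)
    gd = (counts.n_loop * t_loop + counts.n_stempairs * t_stem * c / 2.0) / (
        counts.n_loop + counts.n_stempairs
    )
    flags = []
    if not conv_loop:
        flags.append("loop_saturated")
    if not conv_stem:
        flags.append("stem_saturated")
    return DistanceResult(
        gd=gd,
        lnl=lnl_loop + lnl_stem,
        model=f"{loop_name}+{stem_name}",
        converged=conv_loop and conv_stem,
        t_loop=t_loop,
        t_stem=t_stem,
        lnl_loop=lnl_loop,
        lnl_stem=lnl_stem,
        params={"loop": dict(p_loop.values), "stem": dict(p_stem.values)},
        flags=tuple(flags),
    )


def _fit_fixed_pair(C: np.ndarray, model: SubstModel, cap: float):
    """1-D fit of t for a prebuilt (possibly non-preset) pair model."""
    from scipy.optimize import minimize_scalar

    def neg(t):
        return -pair_log_likelihood(C, model, t)

    C = np.asarray(C)
    if C.sum() - np.trace(C) == 0:
        return 0.0, ModelParams({}, 0), -neg(0.0), True
    res = minimize_scalar(neg, bounds=(0.0, cap), method="bounded",
                          options={"xatol": 1e-10})
    t_hat = float(res.x)
    converged = not (t_hat >= 0.999 * cap and neg(cap) < neg(0.995 * cap))
    return t_hat, ModelParams({}, 0), -float(res.fun), converged


def ml_distance_pair_model(
    counts: SitePatternCounts, model: SubstModel, cap: float = DISTANCE_CAP
) -> tuple[float, float, bool]:
    """Stem-partition-only fit of a fixed prebuilt pair model (diagnostic)."""
    t, _p, lnl, conv = _fit_fixed_pair(counts.stem_counts, model, cap)
    return t, lnl, conv


def gd_ratio(gd_rna: DistanceResult, gd_dna: DistanceResult) -> float:
    """GD_RNA / GD_DNA; undefined when GD_DNA is zero."""
    if gd_dna.gd <= 0:
        raise UndefinedRatioError("GD_DNA is zero; GD ratio undefined")
    return gd_rna.gd / gd_dna.gd
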