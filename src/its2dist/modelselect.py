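"""Mixed-model grid fitting, cross-state-space likelihood correction, AICc.

Likelihoods fitted on different stem state spaces are not directly
comparable: a 7-state model lumps the ten mismatch dinucleotides into one MM
state, so its likelihood lives on a coarser sample space than a 16-state
model's.  Spreading the lumped MM probability uniformly over the ten
mismatch dinucleotides multiplies the likelihood by (1/10) per MM
observation, which puts every fit on the common 16-state sample space:

    lnL_corrected = lnL + n_MM * ln(1/10)        (7-state stem models)

4-state likelihoods on stem nucleotides are already on the dinucleotide
sample space by independence and need no correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .distance import (
    DistanceResult,
    SitePatternCounts,
    count_patterns,
    ml_distance_dna,
    ml_distance_mixed,
)
from .errors import RnaModelNotApplicableError
from .models import n_freq_params, n_rate_params
from .seqstruct import Alignment, PartitionMask

__all__ = ["ModelFit", "correct_likelihood", "aicc", "grid_search",
           "DEFAULT_LOOP_ROSTER", "DEFAULT_STEM_ROSTER", "DEFAULT_DNA_ROSTER"]

DEFAULT_LOOP_ROSTER = ("HKY85", "REV")
DEFAULT_STEM_ROSTER = ("RNA7A", "RNA7G", "RNA16")
DEFAULT_DNA_ROSTER = ("HKY85", "REV")

_N_MISMATCH = 10


@dataclass(frozen=True)
class ModelFit:
    """One fitted model combination with comparable likelihood and AICc."""

    loop_model: str
    stem_model: Optional[str]  # None for a pure DNA fit
    lnl_raw: float
    lnl_corrected: float
    k: int
    n: int
    aicc: float
    result: DistanceResult

    @property
    def label(self) -> str:
        return self.loop_model if self.stem_model is None else (
            f"{self.loop_model}+{self.stem_model}"
        )


def correct_likelihood(lnl: float, stem_space: int, n_mm_observations: int) -> float:
    """Place a stem likelihood on the 16-state sample space.

    7-state fits lose ln(10) per observation of the lumped MM state; 16-state
    (and 4-state independent-site) fits are returned unchanged.
    """
    if n_mm_observations < 0:
        raise ValueError("negative MM observation count")
    if stem_space == 7:
        return lnl + n_mm_observations * math.log(1.0 / _N_MISMATCH)
    if stem_space in (4, 16):
        return lnl
    raise ValueError(f"stem state space must be 4, 7 or 16, got {stem_space}")


def aicc(lnl: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _k_mixed(loop_model: str, stem_model: str) -> int:
    # substitution + frequency free parameters + 2 branch lengths
    return (
        n_rate_params(loop_model) + n_freq_params(loop_model)
        + n_rate_params(stem_model) + n_freq_params(stem_model)
        + 2
    )


def _k_pure(model: str) -> int:
    return n_rate_params(model) + n_freq_params(model) + 1


def grid_search(
    aln2: Alignment,
    mask: PartitionMask,
    loop_roster: Sequence[str] = DEFAULT_LOOP_ROSTER,
    stem_roster: Sequence[str] = DEFAULT_STEM_ROSTER,
    dna_roster: Sequence[str] = DEFAULT_DNA_ROSTER,
    max_iter_stem: int = 500,
) -> list[ModelFit]:
    """Fit every loop-model x stem-model combination plus pure DNA models.

    Returns fits sorted by AICc ascending, ties broken by model-name order.
    ``n`` for AICc is the number of usable nucleotide columns (pair-columns
    count 2).  Combinations whose AICc is undefined (n <= k+1) are retained
    with aicc = +inf so the ranking never silently drops a fitted model.
    """
    counts7 = count_patterns(aln2, mask, space=7)
    counts16 = count_patterns(aln2, mask, space=16)
    if counts7.n_loop == 0 or counts7.n_stempairs == 0:
        raise RnaModelNotApplicableError(
            "RNA model not applicable: empty stem or loop partition"
        )
    n = counts7.n_nucleotide_sites
    fits: list[ModelFit] = []
    for loop_model in loop_roster:
        for stem_model in stem_roster:
            space = 7 if stem_model.startswith("RNA7") else 16
            counts = counts7 if space == 7 else counts16
            res = ml_distance_mixed(
                counts, loop_model, stem_model, max_iter_stem=max_iter_stem
            )
            lnl_corr = correct_likelihood(res.lnl, space, counts.n_mm_observations)
            k = _k_mixed(loop_model, stem_model)
            try:
                a = aicc(lnl_corr, k, n)
            except ValueError:
                a = math.inf
            fits.append(ModelFit(loop_model, stem_model, res.lnl, lnl_corr, k, n, a, res))
    for model in dna_roster:
        res = ml_distance_dna(counts7, model)
        k = _k_pure(model)
        try:
            a = aicc(res.lnl, k, n)
        except ValueError:
            a = math.inf
        fits.append(ModelFit(model, None, res.lnl, res.lnl, k, n, a, res))
    fits.sort(key=lambda f: (f.aicc, f.loop_model, f.stem_model or ""))
    return fits
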