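"""Randomization inference over within-block treatment permutations.

Uncertainty comes from the randomization itself: holding outcomes,
covariates, prior-knowledge flags and the block structure fixed, the
treatment indicator is re-drawn over all assignments the design could have
produced.  Within a matched quartet a main effect admits exactly 6
treated/control labelings — the 4-choose-2 patterns

    (T,T,C,C) (T,C,T,C) (T,C,C,T) (C,C,T,T) (C,T,T,C) (C,T,C,T)

— drawn independently per block.  With B blocks the full null has 6^B
points; it is enumerated exactly when 6^B is small and sampled by
Monte Carlo otherwise (the study's own analysis samples 10,000 draws for
B = 62).

The one-sided "greater" p-value is the raw proportion of permuted
statistics at least as large as the observed one (ties count toward
rejection; no plus-one correction by default, so a statistic larger than
every permuted value reports p = 0; a conservative ``plus_one`` variant is
available).  The observed assignment is not forcibly injected into the
sampled set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .estimators import EstimationError, _demean
from .study_data import MainEffect, Study

logger = logging.getLogger(__name__)

#: Floating-point slack when comparing permuted statistics to the observed
#: one, so that exact ties survive round-off from different summation orders.
TIE_TOL = 1e-12

#: Largest block count for which exact enumeration (6^B evaluations) is
#: allowed by default.
EXACT_BLOCK_LIMIT = 8

#: The 6 within-block treated/control patterns, in canonical order.
BLOCK_PATTERNS: tuple[tuple[str, str, str, str], ...] = (
    ("T", "T", "C", "C"),
    ("T", "C", "T", "C"),
    ("T", "C", "C", "T"),
    ("C", "C", "T", "T"),
    ("C", "T", "T", "C"),
    ("C", "T", "C", "T"),
)

#: Same patterns as a (6, 4) 0/1 matrix.
PATTERN_MATRIX = np.array(
    [[1 if c == "T" else 0 for c in p] for p in BLOCK_PATTERNS], dtype=float
)


class CapacityError(ValueError):
    """Exact enumeration was requested beyond the configured block budget."""


def block_patterns() -> tuple[tuple[str, str, str, str], ...]:
    """The 6 admissible within-block assignments of a main effect (2 T, 2 C)."""
    return BLOCK_PATTERNS


def permute_assignment(
    member_rows: np.ndarray,
    rng: np.random.Generator,
    n_units: Optional[int] = None,
) -> np.ndarray:
    """Draw one admissible assignment: a uniform pattern per block.

    Parameters
    ----------
    member_rows:
        (B, 4) row indices of each block's members (``Study.member_rows``).
    rng:
        NumPy generator; fixing its state fixes the draw.
    n_units:
        Length of the returned indicator (default: 4B).
    """
    member_rows = np.asarray(member_rows, dtype=np.intp)
    B = member_rows.shape[0]
    n = 4 * B if n_units is None else n_units
    idx = rng.integers(0, 6, size=B)
    indicator = np.zeros(n, dtype=float)
    indicator[member_rows] = PATTERN_MATRIX[idx]
    return indicator


@dataclass
class RIResult:
    """Outcome of one randomization test."""

    observed_stat: float
    p_value: float
    n_permutations: int
    mode: str                      # "exact" or "sampled"
    sidedness: str                 # "greater", "less", or "two_sided"
    seed: Optional[int] = None
    n_extreme: int = 0             # permuted statistics counted as >= / <= observed
    n_ties: int = 0                # permuted statistics equal to observed (within TIE_TOL)


def _pvalue(perm: np.ndarray, obs: float, sidedness: str, plus_one: bool) -> tuple[float, int, int]:
    if sidedness == "greater":
        extreme = int((perm >= obs - TIE_TOL).sum())
    elif sidedness == "less":
        extreme = int((perm <= obs + TIE_TOL).sum())
    elif sidedness == "two_sided":
        extreme = int((np.abs(perm) >= abs(obs) - TIE_TOL).sum())
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    ties = int((np.abs(perm - obs) <= TIE_TOL).sum())
    M = perm.size
    p = (extreme + 1) / (M + 1) if plus_one else extreme / M
    return float(p), extreme, ties


def _exact_index_grid(B: int) -> np.ndarray:
    """(6^B, B) array of per-block pattern indices, lexicographic order."""
    return np.array(list(itertools.product(range(6), repeat=B)), dtype=np.intp)


def ri_pvalue(
    study: Study,
    statistic: Callable[[Study, np.ndarray], float],
    effect: MainEffect,
    *,
    M: int = 10_000,
    seed: Union[int, np.random.SeedSequence, None] = None,
    sidedness: str = "greater",
    mode: str = "sampled",
    plus_one: bool = False,
    exact_block_limit: int = EXACT_BLOCK_LIMIT,
) -> RIResult:
    """Randomization p-value for an arbitrary statistic of (study, indicator).

    The statistic is re-evaluated in full for every permutation; only the
    indicator moves.  ``mode="exact"`` enumerates all 6^B assignments
    (refused above ``exact_block_limit`` blocks — use sampling there);
    ``mode="sampled"`` draws M independent assignments.

    The observed statistic is computed from the study's actual assignment
    of ``effect``.
    """
    member_rows = study.member_rows()
    B = member_rows.shape[0]
    n = study.n
    observed_ind = study.indicator_vector(effect)
    obs = float(statistic(study, observed_ind))

    if mode == "exact":
        if B > exact_block_limit:
            raise CapacityError(
                f"exact mode needs 6^{B} evaluations; limit is B <= {exact_block_limit}. "
                "Use mode='sampled'."
            )
        grid = _exact_index_grid(B)
        perm = np.empty(len(grid))
        indicator = np.zeros(n)
        for r, idx in enumerate(grid):
            indicator[member_rows] = PATTERN_MATRIX[idx]
            perm[r] = statistic(study, indicator)
        used_seed = None
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        perm = np.empty(M)
        for r in range(M):
            perm[r] = statistic(study, permute_assignment(member_rows, rng, n))
        used_seed = seed if isinstance(seed, (int, np.integer)) else None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    p, extreme, ties = _pvalue(perm, obs, sidedness, plus_one)
    logger.info(
        "ri_pvalue: mode=%s M=%d seed=%r sidedness=%s obs=%.6g p=%.6g ties=%d",
        mode, perm.size, used_seed, sidedness, obs, p, ties,
    )
    return RIResult(
        observed_stat=obs,
        p_value=p,
        n_permutations=int(perm.size),
        mode=mode,
        sidedness=sidedness,
        seed=used_seed,
        n_extreme=extreme,
        n_ties=ties,
    )


# ---------------------------------------------------------------------------
# fast path for the block fixed-effects slope


def _block_contributions(y: np.ndarray, member_rows: np.ndarray) -> np.ndarray:
    """(B, 6) table: the block-FE slope contribution of each block under
    each of the 6 patterns.

    With balanced quartets the OLS slope equals (sum over treated units of
    the within-block-demeaned outcome) / B, so each block's contribution
    under pattern k is the pattern-weighted sum of its demeaned outcomes.
    This is the same OLS coefficient as ``fit_block_fe_lpm`` — an algebraic
    identity, not an approximation — evaluated without re-solving.
    """
    member_y = y[member_rows]                       # (B, 4)
    demeaned = member_y - member_y.mean(axis=1, keepdims=True)
    return demeaned @ PATTERN_MATRIX.T              # (B, 6)


def ri_pvalue_block_fe(
    study: Study,
    outcome,
    effect: MainEffect,
    *,
    M: int = 10_000,
    seed: Union[int, np.random.SeedSequence, None] = None,
    sidedness: str = "greater",
    mode: str = "sampled",
    plus_one: bool = False,
    exact_block_limit: int = EXACT_BLOCK_LIMIT,
) -> RIResult:
    """Randomization p-value for the block fixed-effects LPM slope,
    vectorized over permutations.

    ``outcome`` is an outcome name or a per-unit vector.  Produces the same
    null distribution as calling :func:`ri_pvalue` with a statistic that
    refits the model per permutation (the closed form is exact for
    balanced quartets), at a small fraction of the cost.
    """
    y = study.outcome_vector(outcome) if isinstance(outcome, str) else np.asarray(outcome, float)
    member_rows = study.member_rows()
    B = member_rows.shape[0]
    contrib = _block_contributions(y, member_rows)

    observed_ind = study.indicator_vector(effect)
    y_t = _demean(y, *_codes_from_member_rows(member_rows, study.n))
    obs = float(y_t @ observed_ind) / B   # sum of demeaned y over treated units / B

    if mode == "exact":
        if B > exact_block_limit:
            raise CapacityError(
                f"exact mode needs 6^{B} evaluations; limit is B <= {exact_block_limit}. "
                "Use mode='sampled'."
            )
        grid = _exact_index_grid(B)                        # (6^B, B)
        perm = contrib[np.arange(B)[None, :], grid].sum(axis=1) / B
        used_seed = None
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, 6, size=(M, B))
        perm = contrib[np.arange(B)[None, :], idx].sum(axis=1) / B
        used_seed = seed if isinstance(seed, (int, np.integer)) else None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    p, extreme, ties = _pvalue(perm, obs, sidedness, plus_one)
    logger.info(
        "ri_pvalue_block_fe: mode=%s M=%d seed=%r sidedness=%s obs=%.6g p=%.6g ties=%d",
        mode, perm.size, used_seed, sidedness, obs, p, ties,
    )
    return RIResult(
        observed_stat=obs,
        p_value=p,
        n_permutations=int(perm.size),
        mode=mode,
        sidedness=sidedness,
        seed=used_seed,
        n_extreme=extreme,
        n_ties=ties,
    )


def _codes_from_member_rows(member_rows: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    B = member_rows.shape[0]
    codes = np.empty(n, dtype=np.intp)
    for b in range(B):
        codes[member_rows[b]] = b
    return codes, B
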