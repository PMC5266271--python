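"""Treatment-effect estimators: group proportions, difference in means, and
block fixed-effects linear probability models.

The workhorse specification regresses a binary outcome y on the main-effect
indicator I plus one fixed effect per matched quartet,

    y_{t,b} = alpha + delta_b + beta * I_{t,b} + eps_{t,b},

with one block absorbed into the constant.  Because every block holds
exactly two treated and two control units, the OLS slope beta-hat equals the
across-block average of within-block treated-minus-control mean differences
— an identity the test suite checks to 1e-10.  The fixed effects are
implemented by within-block demeaning (Frisch-Waugh), which gives the same
coefficients as the explicit dummy-variable solve but stays numerically
stable and fast at 62+ blocks.

No standard errors are produced here on purpose: sampling-based standard
errors are invalid for binary outcomes in small blocked samples, and all
inference is delegated to randomization inference (see :mod:`quartetri.ri`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .study_data import BlockStructureError, MainEffect, TreatmentArm


class EstimationError(ValueError):
    """The regression cannot be solved (collinear or degenerate inputs)."""


def main_effect_indicator(arm: TreatmentArm, effect: MainEffect) -> int:
    """Indicator I: 1 iff ``arm`` includes the factor ``effect``."""
    return effect.indicator(arm)


def _as_vec(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be 1-d")
    return v


def group_proportion(outcome, indicator, group: str = "treated") -> float:
    """Mean outcome among treated (I=1) or control (I=0) units."""
    y = _as_vec(outcome, "outcome")
    ind = _as_vec(indicator, "indicator")
    if y.shape != ind.shape:
        raise ValueError("outcome and indicator lengths differ")
    if group not in ("treated", "control"):
        raise ValueError(f"group must be 'treated' or 'control', got {group!r}")
    mask = ind == 1 if group == "treated" else ind == 0
    if not mask.any():
        raise ValueError(f"empty {group} group")
    return float(y[mask].mean())


def diff_in_means(outcome, indicator) -> float:
    """Treated mean minus control mean — the simple comparison behind the
    bar-chart proportions."""
    return group_proportion(outcome, indicator, "treated") - group_proportion(
        outcome, indicator, "control"
    )


# ---------------------------------------------------------------------------
# block bookkeeping


def _block_codes(blocks: Sequence) -> tuple[np.ndarray, list]:
    """Integer codes (order of first appearance) for per-unit block labels."""
    labels: list = []
    seen: dict = {}
    codes = np.empty(len(blocks), dtype=np.intp)
    for i, b in enumerate(blocks):
        if b not in seen:
            seen[b] = len(labels)
            labels.append(b)
        codes[i] = seen[b]
    return codes, labels


def _demean(values: np.ndarray, codes: np.ndarray, n_blocks: int) -> np.ndarray:
    """Subtract within-block means (works on 1-d or (n, k) arrays)."""
    counts = np.bincount(codes, minlength=n_blocks).astype(float)
    if values.ndim == 1:
        means = np.bincount(codes, weights=values, minlength=n_blocks) / counts
        return values - means[codes]
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        means = np.bincount(codes, weights=values[:, j], minlength=n_blocks) / counts
        out[:, j] = values[:, j] - means[codes]
    return out


def _check_balanced(indicator: np.ndarray, codes: np.ndarray, n_blocks: int) -> None:
    treated = np.bincount(codes, weights=indicator, minlength=n_blocks)
    sizes = np.bincount(codes, minlength=n_blocks)
    bad = np.flatnonzero((sizes != 4) | (treated != 2))
    if bad.size:
        raise BlockStructureError(
            f"blocks not balanced 2 treated / 2 control (code(s) {bad.tolist()})"
        )


@dataclass
class RegressionFit:
    """An OLS fit of a block fixed-effects linear probability model.

    ``alpha`` is the constant (the reference block's level at all regressors
    zero); ``block_effects`` are the remaining B-1 fixed effects relative to
    the reference block; ``betas`` are the slope coefficients;
    ``statistic`` is the slope targeted by randomization inference.
    Fitted values ``alpha + delta_b + X beta`` plus residuals reproduce the
    outcome exactly, and residuals sum to zero within every block.
    """

    alpha: float
    block_effects: dict
    betas: dict[str, float]
    residuals: np.ndarray
    n: int
    statistic: float
    fitted: np.ndarray = field(repr=False, default=None)


def block_fe_beta(outcome: np.ndarray, indicator: np.ndarray, codes: np.ndarray, n_blocks: int) -> float:
    """Slope of the block fixed-effects LPM, by within-block demeaning.

    Minimal fast path used inside permutation loops; assumes codes are
    0..n_blocks-1 and the indicator varies within blocks.
    """
    y_t = _demean(outcome, codes, n_blocks)
    i_t = _demean(indicator, codes, n_blocks)
    denom = float(i_t @ i_t)
    if denom <= 1e-12:
        raise EstimationError("indicator has no within-block variation")
    return float(y_t @ i_t) / denom


def fit_block_fe_lpm(outcome, indicator, blocks) -> RegressionFit:
    """OLS of a binary outcome on a main-effect indicator and block dummies.

    Parameters
    ----------
    outcome, indicator:
        Per-unit vectors; each block must contain exactly 2 treated and
        2 control units.
    blocks:
        Per-unit block labels (any hashable type).

    Returns
    -------
    RegressionFit
        With ``betas == {"treated": beta_hat}`` and ``statistic`` set to
        beta-hat; with balanced quartets this equals the across-block mean
        of within-block treated-minus-control differences.
    """
    y = _as_vec(outcome, "outcome")
    ind = _as_vec(indicator, "indicator")
    if len(blocks) != y.size or ind.size != y.size:
        raise ValueError("outcome, indicator and blocks must align")
    codes, labels = _block_codes(list(blocks))
    B = len(labels)
    _check_balanced(ind, codes, B)
    beta = block_fe_beta(y, ind, codes, B)
    return _assemble_fit(y, ind[:, None], np.array([beta]), ["treated"], codes, labels)


def fit_interaction_lpm(outcome, effect_indicator, know_pss, know_pssh, blocks) -> RegressionFit:
    """The prior-knowledge interaction LPM.

    Regressors: the main-effect indicator, the two baseline prior-knowledge
    flags (entered raw, uncentered), and their products with the indicator,
    plus block dummies and a constant.  Because the flags are uncentered,
    the indicator's coefficient — the inference ``statistic`` — is the
    treatment effect among units with both flags at 0 (no prior knowledge).
    """
    y = _as_vec(outcome, "outcome")
    ind = _as_vec(effect_indicator, "indicator")
    kp = _as_vec(know_pss, "know_pss")
    kh = _as_vec(know_pssh, "know_pssh")
    for v, nm in ((kp, "know_pss"), (kh, "know_pssh")):
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError(f"{nm} must be binary 0/1")
    codes, labels = _block_codes(list(blocks))
    B = len(labels)
    _check_balanced(ind, codes, B)
    names = ["treated", "know_pss", "know_pssh", "know_pss_x_treated", "know_pssh_x_treated"]
    X = np.column_stack([ind, kp, kh, kp * ind, kh * ind])
    Xt = _demean(X, codes, B)
    yt = _demean(y, codes, B)
    # a know flag that never varies contributes nothing: its (demeaned)
    # column is zero, so drop it with coefficient 0 and the model reduces
    # to the plain block-FE fit.  Remaining rank deficiency is genuine
    # collinearity (e.g. identical know flags) and is an error.
    active = np.flatnonzero(np.abs(Xt).max(axis=0) > 1e-12)
    coef_active, _, rank, _ = np.linalg.lstsq(Xt[:, active], yt, rcond=None)
    if rank < active.size:
        raise EstimationError(
            "perfectly collinear regressors in the interaction model "
            f"(rank {rank} < {active.size} varying columns)"
        )
    coef = np.zeros(X.shape[1])
    coef[active] = coef_active
    return _assemble_fit(y, X, coef, names, codes, labels)


def _assemble_fit(
    y: np.ndarray,
    X: np.ndarray,
    coef: np.ndarray,
    names: list[str],
    codes: np.ndarray,
    labels: list,
) -> RegressionFit:
    """Recover the constant and block effects from a demeaned-solve fit."""
    B = len(labels)
    counts = np.bincount(codes, minlength=B).astype(float)
    ybar = np.bincount(codes, weights=y, minlength=B) / counts
    xb_bar = np.vstack(
        [np.bincount(codes, weights=X[:, j], minlength=B) / counts for j in range(X.shape[1])]
    ).T  # (B, k)
    level = ybar - xb_bar @ coef          # alpha + delta_b per block
    alpha = float(level[0])               # first-appearing block is the reference
    deltas = {labels[b]: float(level[b] - alpha) for b in range(1, B)}
    fitted = level[codes] + X @ coef
    residuals = y - fitted
    return RegressionFit(
        alpha=alpha,
        block_effects=deltas,
        betas={nm: float(c) for nm, c in zip(names, coef)},
        residuals=residuals,
        n=y.size,
        statistic=float(coef[0]),
        fitted=fitted,
    )
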