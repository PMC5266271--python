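"""Synthetic baseline and outcome generators with recoverable effects.

These generators emulate the two tables the analysis consumes — a baseline
covariate table for the design stage and an outcome table in the deposited
CSV dialect for the inference stage — with the statistical structure the
method assumes: mixed continuous/binary covariates (optionally clustered,
for matching-quality tests), quartet blocks, balanced factorial arms, and
binary quiz outcomes produced by an additive linear-probability model:

    p = base_rate(outcome)
        + sum over effects of I(arm, effect) * [direct + cross shifts]
        + know-flag main shifts + know-flag-by-treatment shifts,

clamped to [0.01, 0.99] (clamping is counted and logged).  Outcome
generation is additive on the probability scale on purpose: the estimand of
the block fixed-effects LPM is then exactly the configured shift, so
parameter-recovery experiments compare estimate and truth on the same
scale.

Default effect magnitudes sit near the published point estimates of the
motivating trial (e.g. a 0.28 shift of ``store1`` under the storage
treatment, base rate 0.60) so that a default simulation looks like the
study the package replicates; the covariate marginals are plausible
stand-ins, not published quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import design as _design
from .study_data import (
    OUTCOME_NAMES,
    BlockStructureError,
    MainEffect,
    Study,
    UnitRecord,
    write_s1_csv,
)

logger = logging.getLogger(__name__)

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, None]

#: Probability floor/ceiling for generated outcomes.
CLAMP = (0.01, 0.99)


@dataclass
class BaselineConfig:
    """Configuration of the synthetic baseline covariate table.

    ``n_units`` defaults to 248, the size of the motivating trial.  With
    ``n_clusters`` > 1 the continuous covariates receive cluster-specific
    offsets of ``cluster_sep`` standard deviations, giving the matcher real
    structure to find (used by matching-quality tests); ``cluster_sep=0``
    makes the cluster label pure noise.
    """

    n_units: int = 248
    n_clusters: int = 1
    cluster_sep: float = 0.0
    seed: SeedLike = None


#: Covariates produced by :func:`generate_baseline`: household demographics,
#: potato production, welfare, and market access.
BASELINE_COLUMNS = (
    "hh_size",
    "head_age",
    "head_female",
    "potato_area",
    "past_extension",
    "log_yield",
    "log_welfare_pc",
    "dist_input_dealer",
    "credit_access",
)

# (name, nominal sd) of the continuous columns that cluster offsets act on
_CONTINUOUS = (
    ("hh_size", 2.0),
    ("head_age", 12.0),
    ("potato_area", 0.5),
    ("log_yield", 0.8),
    ("log_welfare_pc", 0.7),
    ("dist_input_dealer", 3.5),
)


def generate_baseline(config: Optional[BaselineConfig] = None) -> list[UnitRecord]:
    """Draw a complete synthetic baseline covariate table.

    Returns ``config.n_units`` unit records (covariates only, ids 0..n-1),
    reproducible under ``config.seed``.  The cluster label, when clusters
    are requested, is stored under metadata key ``_cluster`` on each
    record's covariate dict — it is *not* a matching covariate and callers
    that standardize covariates should drop it (``covariate_frame`` sees it
    only if left in place; :func:`generate_baseline` therefore keeps it in a
    separate attribute-free dict entry prefixed with an underscore which
    :func:`strip_cluster` removes).
    """
    cfg = config or BaselineConfig()
    if cfg.n_units < 4:
        raise ValueError("n_units must be >= 4")
    rng = _rng(cfg.seed)
    n = cfg.n_units

    cols = {
        "hh_size": 1.0 + rng.poisson(4.0, n),
        "head_age": np.clip(np.round(rng.normal(45.0, 12.0, n)), 18, 90),
        "head_female": rng.binomial(1, 0.25, n).astype(float),
        "potato_area": rng.lognormal(-0.7, 0.8, n),
        "past_extension": rng.binomial(1, 0.30, n).astype(float),
        "log_yield": rng.normal(7.0, 0.8, n),
        "log_welfare_pc": rng.normal(13.0, 0.7, n),
        "dist_input_dealer": rng.gamma(2.0, 2.5, n),
        "credit_access": rng.binomial(1, 0.35, n).astype(float),
    }

    cluster = np.zeros(n, dtype=int)
    if cfg.n_clusters > 1:
        cluster = rng.integers(0, cfg.n_clusters, n)
        centers = rng.normal(0.0, 1.0, size=(cfg.n_clusters, len(_CONTINUOUS)))
        for j, (name, sd) in enumerate(_CONTINUOUS):
            cols[name] = cols[name] + cfg.cluster_sep * sd * centers[cluster, j]

    units = []
    for i in range(n):
        cov = {k: float(v[i]) for k, v in cols.items()}
        if cfg.n_clusters > 1:
            cov["_cluster"] = float(cluster[i])
        units.append(UnitRecord(unit_id=i, covariates=cov))
    return units


def strip_cluster(units: Sequence[UnitRecord]) -> list[UnitRecord]:
    """Drop the latent ``_cluster`` label before matching."""
    out = []
    for u in units:
        cov = {k: v for k, v in u.covariates.items() if not k.startswith("_")}
        out.append(UnitRecord(unit_id=u.unit_id, covariates=cov))
    return out


@dataclass
class EffectConfig:
    """Generative truth for the outcome model.

    ``direct_effect`` holds the featured-treatment shifts (the effect of the
    video on the questions it covers); ``cross_effect`` holds shifts of the
    *other* questions — the "general knowledge" channel.  Both are keyed
    ``(MainEffect, outcome_name)`` and enter identically through the arm's
    main-effect indicators; the split is semantic.  ``know_main`` shifts
    baseline correctness per prior-knowledge flag; ``know_by_treatment``
    (keyed ``(flag_name, MainEffect)``) adds a knowledge-by-treatment
    interaction.  All shifts are additive probability points.
    """

    base_rate: dict[str, float] = field(
        default_factory=lambda: {
            "sel1": 0.77, "sel2": 0.89, "store1": 0.60,
            "store2": 0.95, "gen1": 0.55, "gen2": 0.50,
        }
    )
    direct_effect: dict[tuple[MainEffect, str], float] = field(
        default_factory=lambda: {
            (MainEffect.PSS, "sel1"): 0.09,
            (MainEffect.PSS, "sel2"): 0.07,
            (MainEffect.PSSH, "store1"): 0.28,
            (MainEffect.PSSH, "store2"): 0.02,
        }
    )
    cross_effect: dict[tuple[MainEffect, str], float] = field(
        default_factory=lambda: {
            (MainEffect.PSS, "store1"): 0.28,
            (MainEffect.PSS, "store2"): 0.02,
            (MainEffect.PSS, "gen1"): 0.13,
            (MainEffect.PSS, "gen2"): 0.17,
            (MainEffect.PSSH, "sel1"): 0.07,
            (MainEffect.PSSH, "sel2"): 0.08,
            (MainEffect.PSSH, "gen1"): 0.08,
            (MainEffect.PSSH, "gen2"): 0.28,
        }
    )
    know_prevalence: tuple[float, float] = (0.5, 0.5)
    know_main: dict[str, float] = field(
        default_factory=lambda: {"know_pss": 0.0, "know_pssh": 0.0}
    )
    know_by_treatment: dict[tuple[str, MainEffect], float] = field(default_factory=dict)
    seed: SeedLike = None

    @classmethod
    def null(cls, seed: SeedLike = None) -> "EffectConfig":
        """Sharp-null truth: every treatment-related shift is exactly zero."""
        return cls(direct_effect={}, cross_effect={}, know_main={}, know_by_treatment={}, seed=seed)

    def total_shift(self, effect: MainEffect, outcome: str) -> float:
        """Marginal treatment shift of ``outcome`` under ``effect`` for a
        unit without prior knowledge (direct + cross)."""
        return self.direct_effect.get((effect, outcome), 0.0) + self.cross_effect.get(
            (effect, outcome), 0.0
        )


def generate_outcomes(
    units: Sequence[UnitRecord],
    effects: Optional[EffectConfig] = None,
    seed: SeedLike = None,
) -> Study:
    """Draw know flags and quiz outcomes for units with assigned arms.

    Each outcome is Bernoulli with probability
    ``clamp(base + treatment shifts + knowledge shifts)``; clamping events
    are counted in the returned study's ``metadata["n_clamped"]`` and
    logged.  ``seed`` overrides ``effects.seed`` when given.
    """
    cfg = effects or EffectConfig()
    rng = _rng(seed if seed is not None else cfg.seed)
    if any(u.arm is None or u.block_id is None for u in units):
        raise BlockStructureError("all units need an arm and a block before outcomes")

    p_kp, p_kh = cfg.know_prevalence
    n_clamped = 0
    out_units = []
    for u in units:
        kp = int(rng.random() < p_kp)
        kh = int(rng.random() < p_kh)
        outcomes = {}
        for name in OUTCOME_NAMES:
            p = cfg.base_rate.get(name, 0.5)
            for eff in MainEffect:
                ind = eff.indicator(u.arm)
                if ind:
                    p += cfg.direct_effect.get((eff, name), 0.0)
                    p += cfg.cross_effect.get((eff, name), 0.0)
                    p += kp * cfg.know_by_treatment.get(("know_pss", eff), 0.0)
                    p += kh * cfg.know_by_treatment.get(("know_pssh", eff), 0.0)
            p += kp * cfg.know_main.get("know_pss", 0.0)
            p += kh * cfg.know_main.get("know_pssh", 0.0)
            clamped = min(max(p, CLAMP[0]), CLAMP[1])
            if clamped != p:
                n_clamped += 1
            outcomes[name] = int(rng.random() < clamped)
        out_units.append(
            UnitRecord(
                unit_id=u.unit_id,
                covariates=dict(u.covariates),
                block_id=u.block_id,
                arm=u.arm,
                outcomes=outcomes,
                know_pss=kp,
                know_pssh=kh,
            )
        )
    if n_clamped:
        logger.warning("generate_outcomes: clamped %d unit-outcome probabilities to %s", n_clamped, CLAMP)
    study = Study.from_units(out_units, metadata={"synthetic": True, "n_clamped": n_clamped})
    return study


def simulate_study(
    n_units: int = 248,
    effects: Optional[EffectConfig] = None,
    baseline: Optional[BaselineConfig] = None,
    seed: SeedLike = None,
    *,
    neighbor: str = "seed-unit",
) -> Study:
    """Full synthetic pipeline: baseline -> matched quartets -> arms -> outcomes.

    One seed drives three independent substreams (baseline covariates,
    design randomness, outcome noise), so the entire study is reproducible
    from a single integer.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    base_ss, design_ss, outcome_ss = ss.spawn(3)
    cfg = baseline or BaselineConfig(n_units=n_units)
    cfg = BaselineConfig(
        n_units=cfg.n_units, n_clusters=cfg.n_clusters,
        cluster_sep=cfg.cluster_sep, seed=np.random.default_rng(base_ss),
    )
    units = strip_cluster(generate_baseline(cfg))
    designed = _design.design_experiment(units, design_ss, neighbor=neighbor)
    return generate_outcomes(designed.units, effects, seed=np.random.default_rng(outcome_ss))


def emulate_s1(study: Study, path) -> None:
    """Write a complete synthetic study as a deposited-dialect CSV.

    The file has the arm-label column (spellings ``Sel+Store``/``Store``/
    ``Sel``/``Ctrl``), six TRUE/FALSE quiz columns, the block number and the
    two prior-knowledge flags, and reads back identically with
    ``read_s1_csv`` under the default column map.
    """
    write_s1_csv(study, path)


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
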