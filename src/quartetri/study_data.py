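"""Domain types and file I/O for a matched-quartet 2x2 factorial knowledge trial.

The study this package models randomizes two informational treatments —
Positive Seed Selection (PSS) and Proper Seed Storage and Handling (PSSH) —
in a full 2x2 factorial within blocks of four units matched on baseline
covariates.  Each block receives every factorial arm exactly once, so each
main effect splits every block into two treated and two control units.

This module holds the shared vocabulary: treatment arms, main effects,
unit records, blocks, the :class:`Study` container, the delimited-text
dialect used by the study's deposited outcome file, and the pre-registered
low-variation outcome screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six quiz outcomes, in canonical order: two on seed selection, two on
#: storage/handling, and two "general" questions not explicitly covered by
#: either video.
OUTCOME_NAMES: tuple[str, ...] = ("sel1", "sel2", "store1", "store2", "gen1", "gen2")

#: Default column names used when reading/writing the deposited outcome-file
#: dialect.  The file itself ships without a documented header, so these are
#: overridable via ``column_map``.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "arm": "treatment",
    "sel1": "sel1",
    "sel2": "sel2",
    "store1": "store1",
    "store2": "store2",
    "gen1": "gen1",
    "gen2": "gen2",
    "block": "block",
    "know_pss": "know_sel",
    "know_pssh": "know_store",
}

#: Modal-share threshold of the pre-registered low-variation outcome screen.
LOW_VARIATION_THRESHOLD: float = 0.95


class ColumnMapError(KeyError):
    """A required column is missing from the file or the column map."""


class StudyParseError(ValueError):
    """A cell could not be parsed (unknown arm label, bad binary code, NA)."""


class BlockStructureError(ValueError):
    """Blocks violate the quartet / one-arm-per-block structure."""


class TreatmentArm(Enum):
    """One of the four factorial conditions."""

    CTRL = "Ctrl"
    SEL = "Sel"
    STORE = "Store"
    SEL_STORE = "Sel+Store"

    @property
    def label(self) -> str:
        """The arm label as written in the deposited data file."""
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "TreatmentArm":
        key = str(label).strip().lower()
        try:
            return _ARM_BY_LABEL[key]
        except KeyError:
            raise StudyParseError(f"unknown treatment arm label: {label!r}") from None


_ARM_BY_LABEL = {a.value.lower(): a for a in TreatmentArm}

ARMS: tuple[TreatmentArm, ...] = (
    TreatmentArm.CTRL,
    TreatmentArm.SEL,
    TreatmentArm.STORE,
    TreatmentArm.SEL_STORE,
)


class MainEffect(Enum):
    """The two factorial main effects.

    PSS pools the two arms that saw the seed-selection video
    (``Sel``, ``Sel+Store``); PSSH pools the two arms that saw the
    storage-and-handling video (``Store``, ``Sel+Store``).
    """

    PSS = "PSS"
    PSSH = "PSSH"

    def indicator(self, arm: TreatmentArm) -> int:
        """Main-effect indicator I: 1 iff ``arm`` includes this factor."""
        if self is MainEffect.PSS:
            return int(arm in (TreatmentArm.SEL, TreatmentArm.SEL_STORE))
        return int(arm in (TreatmentArm.STORE, TreatmentArm.SEL_STORE))


@dataclass(frozen=True)
class Block:
    """An ordered quartet of unit identifiers sharing one randomization stratum."""

    block_id: Hashable
    member_ids: tuple[Hashable, Hashable, Hashable, Hashable]

    def __post_init__(self) -> None:
        if len(self.member_ids) != 4:
            raise BlockStructureError(
                f"block {self.block_id!r} has {len(self.member_ids)} members, expected 4"
            )
        if len(set(self.member_ids)) != 4:
            raise BlockStructureError(f"block {self.block_id!r} has duplicate members")


@dataclass
class UnitRecord:
    """One experimental unit: covariates, design slots, and quiz outcomes.

    ``covariates`` is a free-form named mapping — the design stage
    standardizes whatever covariates are present, giving each equal weight.
    ``outcomes`` holds the six binary quiz answers when the unit has been
    through the endline quiz; ``know_pss``/``know_pssh`` are baseline
    prior-knowledge flags.
    """

    unit_id: Hashable
    covariates: dict[str, float] = field(default_factory=dict)
    block_id: Optional[Hashable] = None
    arm: Optional[TreatmentArm] = None
    outcomes: dict[str, int] = field(default_factory=dict)
    know_pss: Optional[int] = None
    know_pssh: Optional[int] = None


@dataclass
class Study:
    """A collection of units with their block structure.

    Blocks must partition the units; when arms are assigned, every block
    carries each of the four factorial arms exactly once.
    """

    units: list[UnitRecord]
    blocks: list[Block] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------

    @classmethod
    def from_units(cls, units: Sequence[UnitRecord], metadata: Optional[dict] = None) -> "Study":
        """Build a Study, deriving blocks from the units' ``block_id`` fields."""
        order: dict[Hashable, list[Hashable]] = {}
        for u in units:
            if u.block_id is None:
                raise BlockStructureError(f"unit {u.unit_id!r} has no block_id")
            order.setdefault(u.block_id, []).append(u.unit_id)
        bad = {b: len(m) for b, m in order.items() if len(m) != 4}
        if bad:
            raise BlockStructureError(f"blocks without exactly 4 members: {bad}")
        blocks = [Block(b, tuple(m)) for b, m in order.items()]
        study = cls(units=list(units), blocks=blocks, metadata=metadata or {})
        study.validate()
        return study

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        """Check the partition and one-arm-per-block invariants."""
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise BlockStructureError("duplicate unit_ids in study")
        covered: set[Hashable] = set()
        by_id = {u.unit_id: u for u in self.units}
        for blk in self.blocks:
            for m in blk.member_ids:
                if m in covered:
                    raise BlockStructureError(f"unit {m!r} appears in more than one block")
                if m not in by_id:
                    raise BlockStructureError(f"block {blk.block_id!r} references unknown unit {m!r}")
                covered.add(m)
        if covered != set(ids):
            missing = set(ids) - covered
            raise BlockStructureError(f"units not covered by any block: {sorted(map(str, missing))[:5]}")
        # one arm of each kind per block, when arms are assigned at all
        if any(u.arm is not None for u in self.units):
            offending = []
            for blk in self.blocks:
                arms = sorted(
                    (by_id[m].arm.label if by_id[m].arm is not None else "?")
                    for m in blk.member_ids
                )
                if arms != sorted(a.label for a in ARMS):
                    offending.append(blk.block_id)
            if offending:
                raise BlockStructureError(
                    f"blocks without each arm exactly once: {offending}"
                )

    # -- vector views used by estimation and inference ----------------

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def unit_index(self) -> dict[Hashable, int]:
        return {u.unit_id: i for i, u in enumerate(self.units)}

    def outcome_vector(self, name: str) -> np.ndarray:
        if name not in OUTCOME_NAMES:
            raise KeyError(f"unknown outcome {name!r}; expected one of {OUTCOME_NAMES}")
        try:
            return np.array([u.outcomes[name] for u in self.units], dtype=float)
        except KeyError:
            missing = [u.unit_id for u in self.units if name not in u.outcomes]
            raise StudyParseError(f"outcome {name!r} missing for units {missing[:5]}") from None

    def arm_vector(self) -> list[TreatmentArm]:
        arms = []
        for u in self.units:
            if u.arm is None:
                raise BlockStructureError(f"unit {u.unit_id!r} has no assigned arm")
            arms.append(u.arm)
        return arms

    def indicator_vector(self, effect: MainEffect) -> np.ndarray:
        """Per-unit main-effect indicator I, aligned with ``units``."""
        return np.array([effect.indicator(a) for a in self.arm_vector()], dtype=float)

    def block_labels(self) -> np.ndarray:
        """Per-unit block label, aligned with ``units``."""
        by_unit: dict[Hashable, Hashable] = {}
        for blk in self.blocks:
            for m in blk.member_ids:
                by_unit[m] = blk.block_id
        return np.array([by_unit[u.unit_id] for u in self.units], dtype=object)

    def member_rows(self) -> np.ndarray:
        """(B, 4) array of row indices into ``units``, one row per block.

        Column order follows each block's ``member_ids`` order, which is the
        unit ordering the within-block permutation patterns act on.
        """
        idx = self.unit_index()
        return np.array(
            [[idx[m] for m in blk.member_ids] for blk in self.blocks], dtype=np.intp
        )

    def know_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        def grab(attr: str) -> np.ndarray:
            vals = [getattr(u, attr) for u in self.units]
            if any(v is None for v in vals):
                raise StudyParseError(f"{attr} missing for some units")
            return np.array(vals, dtype=float)

        return grab("know_pss"), grab("know_pssh")


# ---------------------------------------------------------------------------
# binary parsing helpers

# exactly TRUE/FALSE (any case) and 1/0 are binary; anything else errors
_TRUE = {"true", "1"}
_FALSE = {"false", "0"}


def _parse_binary(value: object, *, row: int, column: str) -> int:
    """Parse TRUE/FALSE/True/False/1/0 to {0,1}; anything else is an error."""
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return 1
    if s in _FALSE:
        return 0
    raise StudyParseError(
        f"row {row}: cannot parse {value!r} in column {column!r} as binary"
    )


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


# ---------------------------------------------------------------------------
# the deposited-file dialect


def read_s1_csv(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    *,
    sep: str = ",",
    drop_incomplete: bool = False,
) -> Study:
    """Read an outcome table in the study's deposited-CSV dialect.

    The dialect: one row per unit; a treatment-arm column with labels
    ``Ctrl``/``Sel``/``Store``/``Sel+Store``; six TRUE/FALSE quiz columns
    ``sel1`` … ``gen2``; a block-number column; and two prior-knowledge
    flags.  ``column_map`` maps the logical names (keys of
    :data:`DEFAULT_COLUMN_MAP`) to the file's actual header names.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Overrides for :data:`DEFAULT_COLUMN_MAP`; partial maps are merged
        over the defaults.
    sep:
        Field delimiter (comma by default).
    drop_incomplete:
        If True, rows with missing outcome/flag cells are dropped with a
        logged count instead of raising.

    Raises
    ------
    ColumnMapError
        If a mapped column is absent from the file.
    StudyParseError
        On unknown arm labels, unparseable binaries, or (by default)
        missing values; the row number is named.
    BlockStructureError
        If any block does not have exactly 4 members, or arms are not
        balanced within a block.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for logical, actual in cmap.items():
        if actual not in df.columns:
            raise ColumnMapError(
                f"column {actual!r} (for {logical!r}) not found; file has {list(df.columns)}"
            )

    binary_fields = list(OUTCOME_NAMES) + ["know_pss", "know_pssh"]
    units: list[UnitRecord] = []
    n_dropped = 0
    for row, rec in enumerate(df.to_dict("records")):
        cells = {lg: rec[cmap[lg]] for lg in cmap}
        if any(_is_missing(cells[f]) for f in binary_fields + ["arm", "block"]):
            if drop_incomplete:
                n_dropped += 1
                continue
            bad = [f for f in cmap if _is_missing(cells[f])]
            raise StudyParseError(f"row {row}: missing value(s) in {bad}")
        try:
            arm = TreatmentArm.from_label(cells["arm"])
        except StudyParseError as e:
            raise StudyParseError(f"row {row}: {e}") from None
        outcomes = {
            name: _parse_binary(cells[name], row=row, column=cmap[name])
            for name in OUTCOME_NAMES
        }
        units.append(
            UnitRecord(
                unit_id=row,
                block_id=str(cells["block"]).strip(),
                arm=arm,
                outcomes=outcomes,
                know_pss=_parse_binary(cells["know_pss"], row=row, column=cmap["know_pss"]),
                know_pssh=_parse_binary(cells["know_pssh"], row=row, column=cmap["know_pssh"]),
            )
        )
    if n_dropped:
        logger.warning("read_s1_csv: dropped %d incomplete rows", n_dropped)

    study = Study.from_units(
        units,
        metadata={"source": str(path), "column_map": cmap, "n_dropped": n_dropped},
    )
    return study


def write_s1_csv(
    study: Study,
    path,
    column_map: Optional[Mapping[str, str]] = None,
    *,
    sep: str = ",",
) -> None:
    """Write a complete study back out in the deposited-CSV dialect.

    Binary cells are emitted as ``TRUE``/``FALSE``; arm labels use the
    canonical spellings.  ``read_s1_csv(write_s1_csv(study))`` round-trips
    arm, block, outcome and prior-knowledge content exactly.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    def tf(v: int) -> str:
        return "TRUE" if int(v) == 1 else "FALSE"

    rows = []
    for u in study.units:
        if u.arm is None or u.block_id is None:
            raise BlockStructureError(f"unit {u.unit_id!r} lacks arm or block; cannot write")
        missing = [n for n in OUTCOME_NAMES if n not in u.outcomes]
        if missing or u.know_pss is None or u.know_pssh is None:
            raise StudyParseError(f"unit {u.unit_id!r} has incomplete outcomes/flags: {missing}")
        row = {cmap["arm"]: u.arm.label, }
        for name in OUTCOME_NAMES:
            row[cmap[name]] = tf(u.outcomes[name])
        row[cmap["block"]] = u.block_id
        row[cmap["know_pss"]] = tf(u.know_pss)
        row[cmap["know_pssh"]] = tf(u.know_pssh)
        rows.append(row)
    cols = [cmap["arm"], *[cmap[n] for n in OUTCOME_NAMES], cmap["block"], cmap["know_pss"], cmap["know_pssh"]]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# pre-registered outcome screen


def low_variation_flag(
    outcome_values: Iterable[float], threshold: float = LOW_VARIATION_THRESHOLD
) -> bool:
    """Flag an outcome whose modal value covers at least ``threshold`` of units.

    The screen is pre-registered: binary outcomes where >= 95% of
    observations share the same value carry almost no information and are
    flagged for discard.  The share is computed on the full sample and the
    comparison is inclusive; the flag is invariant to relabeling 0 <-> 1.
    """
    v = np.asarray(list(outcome_values), dtype=float)
    if v.size == 0:
        raise ValueError("low_variation_flag: empty outcome vector")
    if not np.isin(v, (0.0, 1.0)).all():
        raise ValueError("low_variation_flag: values must be binary 0/1")
    share_ones = v.mean()
    return bool(max(share_ones, 1.0 - share_ones) >= threshold)
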