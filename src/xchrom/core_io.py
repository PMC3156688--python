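"""Data model and tabular I/O for chromosome-level expression analysis.

All expression values are stored as log2 signal intensities (``LOG_BASE = 2``);
one qPCR cycle likewise corresponds to one log2 unit of template abundance.
Chromosome arms follow the Drosophila melanogaster karyotype: the X, the four
major autosomal arms (2L, 2R, 3L, 3R), and the small heterochromatic fourth
("dot") chromosome.  Whenever an aggregate autosomal ("A") class is formed the
fourth chromosome is excluded, because its heterochromatic regulation is not
representative of euchromatic autosomal behaviour.

File formats are plain tab-separated text:

* expression tables — columns ``probe_id``, ``arm``, optional ``gene_symbol``
  and ``coordinate``, then one column per sample named ``<condition>:<rep>``;
* RPKM tables — columns ``gene_id``, ``arm``, ``rpkm``;
* Ct tables — columns ``gene``, ``dissection``, ``plate``, ``ct``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("xchrom")

LOG_BASE = 2

#: Linear-intensity floor applied before re-logging averaged replicate spots,
#: guarding against background-subtracted intensities at or below zero.
LINEAR_FLOOR = 1e-6

ARMS = ("X", "2L", "2R", "3L", "3R", "4")
#: Arms contributing to the aggregate autosome class.  Never includes arm 4.
AUTOSOME_ARMS = ("2L", "2R", "3L", "3R")

CONDITIONS = (
    "male_thorax",
    "female_thorax",
    "premeiotic",
    "premeiotic_with_sheath",
    "meiotic",
    "postmeiotic",
    "control_cells",
    "msl2_knockdown",
    "testis",
    "ovary",
    "bam_testis",
    "bam_ovary",
)

DISSECTIONS = ("Ps", "Pn", "M")


class AnnotationError(ValueError):
    """A probe lacks a valid chromosome-arm annotation."""


class TableParseError(ValueError):
    """A tabular input file violates its declared format."""


class InsufficientDataError(ValueError):
    """Too few observations remain to compute the requested statistic."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 intensities for probes x samples with probe and sample metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Probes on the index (``probe_id``), samples on the columns.  Column
        names are ``<condition>:<replicate>`` sample keys.
    annotation : pandas.DataFrame
        Indexed by ``probe_id``; must carry an ``arm`` column restricted to
        :data:`ARMS`; may carry ``gene_symbol`` and ``coordinate``.
    samples : pandas.DataFrame
        Indexed by sample key, with ``condition`` and ``replicate`` columns.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame
    #: Raw arrays may carry replicate spots of the same probe; such matrices
    #: are only valid as input to :func:`average_replicate_spots`.
    allow_duplicate_probes: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates and not self.allow_duplicate_probes:
            dupes = self.values.index[self.values.index.duplicated()][:5]
            raise AnnotationError(f"duplicate probe ids: {list(dupes)}")
        if not self.values.index.equals(self.annotation.index):
            missing = self.values.index.difference(self.annotation.index)
            raise AnnotationError(
                f"{len(missing)} probes lack annotation (e.g. {list(missing[:3])})"
            )
        bad = set(self.annotation["arm"]) - set(ARMS)
        if bad:
            raise AnnotationError(f"unknown chromosome arm(s): {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise TableParseError("expression values must be finite")
        pairs = list(zip(self.samples["condition"], self.samples["replicate"]))
        if len(pairs) != len(set(pairs)):
            raise TableParseError("(condition, replicate) pairs must be unique")
        unknown = set(self.samples["condition"]) - set(CONDITIONS)
        if unknown:
            raise TableParseError(f"unknown sample condition(s): {sorted(unknown)}")

    # -- convenience accessors ------------------------------------------------

    @property
    def arms(self) -> pd.Series:
        """Chromosome arm per probe, aligned with ``values``."""
        return self.annotation["arm"]

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    def sample_keys(self, condition: str) -> list[str]:
        keys = self.samples.index[self.samples["condition"] == condition]
        if len(keys) == 0:
            raise KeyError(f"condition {condition!r} not present in matrix")
        return list(keys)

    def condition_means(self, condition: str) -> pd.Series:
        """Per-probe arithmetic mean of log2 values over replicates."""
        return self.values[self.sample_keys(condition)].mean(axis=1)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[probe_ids],
            self.annotation.loc[probe_ids],
            self.samples.copy(),
        )


@dataclass
class RpkmTable:
    """Gene-level RPKM values with arm annotation (transcript-summed)."""

    frame: pd.DataFrame  # columns gene_id, arm, rpkm

    def __post_init__(self) -> None:
        required = {"gene_id", "arm", "rpkm"}
        if not required <= set(self.frame.columns):
            raise TableParseError(f"RPKM table needs columns {sorted(required)}")
        bad = set(self.frame["arm"]) - set(ARMS)
        if bad:
            raise AnnotationError(f"unknown chromosome arm(s): {sorted(bad)}")
        if (self.frame["rpkm"] < 0).any() or not np.isfinite(self.frame["rpkm"]).all():
            raise TableParseError("RPKM values must be finite and non-negative")


@dataclass
class CtTable:
    """qPCR threshold-cycle observations, one row per (gene, dissection, plate).

    ``ct`` is the well-averaged threshold cycle for that probe on that plate.
    ``control_genes`` name the normalising controls; every (dissection, plate)
    combination must carry all of them.
    """

    observations: pd.DataFrame  # columns gene, dissection, plate, ct
    control_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.control_genes = frozenset(self.control_genes)
        required = {"gene", "dissection", "plate", "ct"}
        if not required <= set(self.observations.columns):
            raise TableParseError(f"Ct table needs columns {sorted(required)}")
        if (self.observations["ct"] <= 0).any():
            raise TableParseError("Ct values must be positive")
        unknown = set(self.observations["dissection"]) - set(DISSECTIONS)
        if unknown:
            raise TableParseError(f"unknown dissection(s): {sorted(unknown)}")
        genes = set(self.observations["gene"])
        missing = self.control_genes - genes
        if missing:
            raise TableParseError(
                f"control gene(s) absent from Ct table: {sorted(missing)}"
            )
        for (diss, plate), grp in self.observations.groupby(
            ["dissection", "plate"], sort=False
        ):
            absent = self.control_genes - set(grp["gene"])
            if absent:
                raise TableParseError(
                    f"plate {plate!r} dissection {diss!r} lacks control(s) "
                    f"{sorted(absent)}"
                )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_ANNOT_COLS = ("arm", "gene_symbol", "coordinate")


def read_expression_table(path, dialect: str = "generic_tsv") -> ExpressionMatrix:
    """Read a tab-separated expression table into an :class:`ExpressionMatrix`.

    The first column is ``probe_id``; an ``arm`` column is mandatory; every
    remaining non-annotation column is a sample named ``<condition>:<rep>``.
    """
    if dialect != "generic_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in raw.columns:
        raise TableParseError(f"{path}: first column must be probe_id")
    if "arm" not in raw.columns:
        raise AnnotationError(f"{path}: missing arm annotation column")
    raw = raw.set_index("probe_id")
    annot_cols = [c for c in _ANNOT_COLS if c in raw.columns]
    sample_cols = [c for c in raw.columns if c not in annot_cols]
    samples = _parse_sample_keys(sample_cols, path)
    values = raw[sample_cols]
    for col in sample_cols:
        if not pd.api.types.is_numeric_dtype(values[col]):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise TableParseError(
                f"{path}: non-numeric value in column {col!r}, probe {row!r}"
            )
    return ExpressionMatrix(
        values.astype(float),
        raw[annot_cols].copy(),
        samples,
        allow_duplicate_probes=bool(raw.index.has_duplicates),
    )


def _parse_sample_keys(keys, path="<memory>") -> pd.DataFrame:
    conditions, replicates = [], []
    for key in keys:
        cond, sep, rep = str(key).rpartition(":")
        if not sep or not rep.isdigit() or int(rep) < 1:
            raise TableParseError(
                f"{path}: sample column {key!r} is not '<condition>:<replicate>'"
            )
        conditions.append(cond)
        replicates.append(int(rep))
    return pd.DataFrame(
        {"condition": conditions, "replicate": replicates}, index=pd.Index(keys)
    )


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    annot_cols = [c for c in _ANNOT_COLS if c in matrix.annotation.columns]
    out = pd.concat([matrix.annotation[annot_cols], matrix.values], axis=1)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def make_expression_matrix(values: pd.DataFrame, arms: pd.Series) -> ExpressionMatrix:
    """Build a matrix from a values frame whose columns are sample keys."""
    annotation = pd.DataFrame({"arm": arms.reindex(values.index)})
    samples = _parse_sample_keys(list(values.columns))
    return ExpressionMatrix(values, annotation, samples)


def average_replicate_spots(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse duplicate probe rows by averaging on the linear scale.

    Replicate spots of the same probe are averaged as linear intensities
    (signal intensity is linear; the stored values are its log2), then
    re-logged.  Linear intensities are clamped at :data:`LINEAR_FLOOR` first.
    """
    linear = np.maximum(np.exp2(raw.values), LINEAR_FLOOR)
    collapsed = np.log2(linear.groupby(level=0, sort=False).mean())
    annotation = raw.annotation[~raw.annotation.index.duplicated(keep="first")]
    return ExpressionMatrix(
        collapsed, annotation.loc[collapsed.index], raw.samples.copy()
    )


def read_rpkm_table(path) -> RpkmTable:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "arm": str})
    try:
        frame["rpkm"] = pd.to_numeric(frame["rpkm"])
    except (KeyError, ValueError) as exc:
        raise TableParseError(f"{path}: bad RPKM column: {exc}") from exc
    return RpkmTable(frame)


def write_rpkm_table(table: RpkmTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ct_table(path, control_genes=()) -> CtTable:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "dissection": str})
    try:
        frame["ct"] = pd.to_numeric(frame["ct"])
    except (KeyError, ValueError) as exc:
        raise TableParseError(f"{path}: bad ct column: {exc}") from exc
    return CtTable(frame, frozenset(control_genes))


def write_ct_table(table: CtTable, path) -> None:
    table.observations.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Summary-table formatting
# ---------------------------------------------------------------------------


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage with round-half-up at the requested precision.

    >>> percent(741, 1943)
    38.1
    """
    if total == 0:
        return float("nan")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(count) * 100 / Decimal(total)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


def format_count_percent(count: int, total: int) -> str:
    """Render a contingency cell as ``"741 (38.1%)"``."""
    return f"{count:,} ({percent(count, total):.1f}%)"


def parse_count_percent(cell: str) -> tuple[int, float]:
    """Inverse of :func:`format_count_percent` (for round-trip checks)."""
    count_part, _, pct_part = cell.partition(" (")
    return int(count_part.replace(",", "")), float(pct_part.rstrip("%)"))


def write_summary_tables(results: dict, out_dir) -> list[Path]:
    """Write each named result table as ``<name>.tsv`` under ``out_dir``.

    Values in tables named ``*counts*`` are expected to already be formatted
    cells; everything else is written with full float precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in results.items():
        target = out_dir / f"{name}.tsv"
        frame.to_csv(target, sep="\t", float_format="%.10g")
        written.append(target)
        logger.info("wrote %s (%d rows)", target, len(frame))
    return written
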