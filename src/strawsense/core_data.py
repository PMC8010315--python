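"""Domain types, validation and delimited-text I/O for sensory/chemical sample tables.

A dataset is one genotype x harvest observation per row, joining trained-panel
sensory means (0-10 scale), refractometer soluble solids (SSC, %), titratable
acidity (TA), pH, and internal-standard-normalized GC-MS volatile peak areas.
Columns are discovered by prefix: ``sens_<attribute>`` for sensory means,
``chem_ssc`` / ``chem_ta`` / ``chem_ph`` for pooled chemistry, and
``vol_<compound>`` for the volatile block.  Optional panelist-level ratings and
field-replicate chemistry live in sidecar tables next to the main file.

An empty volatile cell means the compound was not detected in that sample
(below detection), which is distinct from a measured zero; downstream stages
may zero-fill via :class:`SchemaConfig.zero_fill_missing_volatiles`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

SENSORY_PREFIX = "sens_"
VOLATILE_PREFIX = "vol_"
CHEM_COLUMNS = {"ssc": "chem_ssc", "ta": "chem_ta", "ph": "chem_ph"}
KEY_COLUMNS = ["sample_id", "genotype", "year", "month"]


@dataclass
class SchemaConfig:
    """Column-mapping and parsing options for :func:`read_dataset`.

    Attributes
    ----------
    delimiter:
        Field separator; comma by default, tab accepted.
    sensory_prefix, volatile_prefix:
        Column-name prefixes identifying the sensory and volatile blocks.
    chem_columns:
        Mapping from canonical chemistry measures (``ssc``, ``ta``, ``ph``)
        to column names.
    zero_fill_missing_volatiles:
        If True (default), absent volatile cells are imputed as 0 before
        scale-sensitive analyses (undetected peaks are below detection);
        the stored dataset keeps them absent either way.
    float_format:
        printf format used when writing numeric cells.  The default ``%.17g``
        round-trips IEEE doubles exactly.
    """

    delimiter: str = ","
    sensory_prefix: str = SENSORY_PREFIX
    volatile_prefix: str = VOLATILE_PREFIX
    chem_columns: Mapping[str, str] = field(default_factory=lambda: dict(CHEM_COLUMNS))
    zero_fill_missing_volatiles: bool = True
    float_format: str = "%.17g"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        """Load a flat key-value (YAML) schema config file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown schema config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class SampleRecord:
    """One genotype x harvest observation.

    ``volatiles`` maps compound name -> nonnegative abundance; a compound that
    was not detected is simply absent from the map.
    """

    sample_id: str
    genotype: str
    year: int
    month: int
    sensory: dict[str, float]
    ssc: float
    ta: float
    ph: float
    volatiles: dict[str, float] = field(default_factory=dict)

    def invariant_violations(self) -> list[tuple[str, object, str]]:
        """Return (field, value, reason) tuples for every violated invariant."""
        bad: list[tuple[str, object, str]] = []
        if not 1 <= self.month <= 12:
            bad.append(("month", self.month, "month must be in 1..12"))
        for name, rating in self.sensory.items():
            if not (math.isfinite(rating) and 0.0 <= rating <= 10.0):
                bad.append((f"sens_{name}", rating, "rating outside [0, 10]"))
        if not (math.isfinite(self.ssc) and self.ssc > 0):
            bad.append(("chem_ssc", self.ssc, "ssc must be > 0"))
        # ta/ph may legitimately be unmeasured (NaN); range-check only when present
        if not math.isnan(self.ta) and not (math.isfinite(self.ta) and self.ta >= 0):
            bad.append(("chem_ta", self.ta, "ta must be >= 0"))
        if not math.isnan(self.ph) and not (math.isfinite(self.ph) and 0 < self.ph < 14):
            bad.append(("chem_ph", self.ph, "ph must be in (0, 14)"))
        for comp, val in self.volatiles.items():
            if not (math.isfinite(val) and val >= 0):
                bad.append((f"vol_{comp}", val, "abundance must be >= 0"))
        return bad


@dataclass
class PanelDataset:
    """A collection of :class:`SampleRecord` plus optional panelist-level
    ratings and replicate-level chemistry, keyed by (genotype, year, month)."""

    records: list[SampleRecord]
    attribute_names: list[str]
    compound_names: list[str]
    panelist_ratings: pd.DataFrame | None = None  # sample_id, panelist_id, attribute, rating
    replicate_chem: pd.DataFrame | None = None  # sample_id, replicate_id, measure, value

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def to_frame(self, zero_fill_volatiles: bool = False) -> pd.DataFrame:
        """Wide per-sample table with prefixed column names.

        Absent volatiles become NaN, or 0 when ``zero_fill_volatiles``.
        """
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "sample_id": r.sample_id,
                "genotype": r.genotype,
                "year": r.year,
                "month": r.month,
            }
            for a in self.attribute_names:
                row[SENSORY_PREFIX + a] = r.sensory.get(a, np.nan)
            row["chem_ssc"] = r.ssc
            row["chem_ta"] = r.ta
            row["chem_ph"] = r.ph
            for c in self.compound_names:
                row[VOLATILE_PREFIX + c] = r.volatiles.get(c, np.nan)
            rows.append(row)
        cols = (
            KEY_COLUMNS
            + [SENSORY_PREFIX + a for a in self.attribute_names]
            + list(CHEM_COLUMNS.values())
            + [VOLATILE_PREFIX + c for c in self.compound_names]
        )
        df = pd.DataFrame(rows, columns=cols)
        if zero_fill_volatiles:
            vol_cols = [VOLATILE_PREFIX + c for c in self.compound_names]
            df[vol_cols] = df[vol_cols].fillna(0.0)
        return df

    def regression_frame(
        self, response: str = "sweetness", predictor: str = "ssc"
    ) -> pd.DataFrame:
        """Per-sample (y, x, month, genotype, year) frame for regression.

        Rows with a missing response or predictor are dropped with a log line
        (the pipeline models whatever samples have both measurements).
        """
        df = self.to_frame()
        ycol = SENSORY_PREFIX + response
        xcol = CHEM_COLUMNS.get(predictor, predictor)
        keep = df[[ycol, xcol]].notna().all(axis=1)
        if (~keep).any():
            dropped = df.loc[~keep, "sample_id"].tolist()
            logger.info(
                "dropping %d rows with missing %s or %s: %s",
                len(dropped), response, predictor, dropped,
            )
        out = df.loc[keep, ["sample_id", "genotype", "year", "month", ycol, xcol]]
        return out.rename(columns={ycol: "y", xcol: "x"}).reset_index(drop=True)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        offenses: list[tuple[int, str, object, str]] = []
        seen: dict[tuple[str, int, int], str] = {}
        ids = set()
        for i, r in enumerate(self.records):
            for col, val, reason in r.invariant_violations():
                offenses.append((i, col, val, reason))
            key = (r.genotype, r.year, r.month)
            if key in seen:
                offenses.append((i, "genotype/year/month", key, "duplicate sample key"))
            seen[key] = r.sample_id
            if r.sample_id in ids:
                offenses.append((i, "sample_id", r.sample_id, "duplicate sample_id"))
            ids.add(r.sample_id)
        if len(set(self.attribute_names)) != len(self.attribute_names):
            raise ValidationError("attribute_names contains duplicates")
        if len(set(self.compound_names)) != len(self.compound_names):
            raise ValidationError("compound_names contains duplicates")
        for table, name in ((self.panelist_ratings, "panelist_ratings"),
                            (self.replicate_chem, "replicate_chem")):
            if table is not None:
                unresolved = set(table["sample_id"]) - ids
                if unresolved:
                    raise ValidationError(
                        f"{name} references unknown sample_ids: {sorted(unresolved)[:5]}"
                    )
        if offenses:
            lines = "; ".join(
                f"record {i} [{col}]={val!r}: {reason}" for i, col, val, reason in offenses[:20]
            )
            raise ValidationError(f"{len(offenses)} invariant violation(s): {lines}", offenses)


# -- I/O -------------------------------------------------------------------


def _sidecar(path: Path, tag: str) -> Path:
    return path.with_name(path.stem + f".{tag}" + path.suffix)


def read_dataset(path: str | Path, schema: SchemaConfig | None = None) -> PanelDataset:
    """Read a delimited sample table (plus sidecars, if present) into a
    :class:`PanelDataset`.

    Raises
    ------
    SchemaError
        if a required column (genotype, year, month, sens_sweetness, chem_ssc)
        is missing.
    ValidationError
        listing offending cells with row numbers, if any value violates the
        typed invariants.
    """
    schema = schema or SchemaConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=schema.delimiter)

    required = ["genotype", "year", "month",
                schema.sensory_prefix + "sweetness", schema.chem_columns["ssc"]]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")

    attr_cols = [c for c in df.columns if c.startswith(schema.sensory_prefix)]
    vol_cols = [c for c in df.columns if c.startswith(schema.volatile_prefix)]
    attribute_names = [c[len(schema.sensory_prefix):] for c in attr_cols]
    compound_names = [c[len(schema.volatile_prefix):] for c in vol_cols]

    records: list[SampleRecord] = []
    parse_failures: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            sid = str(row["sample_id"]) if "sample_id" in df.columns else f"S{i:04d}"
            sensory = {a: float(row[schema.sensory_prefix + a]) for a in attribute_names
                       if pd.notna(row[schema.sensory_prefix + a])}
            volatiles = {c: float(row[schema.volatile_prefix + c]) for c in compound_names
                         if pd.notna(row[schema.volatile_prefix + c])}
            rec = SampleRecord(
                sample_id=sid,
                genotype=str(row["genotype"]),
                year=int(row["year"]),
                month=int(row["month"]),
                sensory=sensory,
                ssc=float(row[schema.chem_columns["ssc"]]),
                ta=float(row.get(schema.chem_columns["ta"], np.nan)),
                ph=float(row.get(schema.chem_columns["ph"], np.nan)),
                volatiles=volatiles,
            )
        except (TypeError, ValueError) as exc:
            parse_failures.append((i, str(exc)))
            continue
        records.append(rec)
    if parse_failures:
        lines = "; ".join(f"row {i}: {msg}" for i, msg in parse_failures[:10])
        raise ValidationError(
            f"{len(parse_failures)} row(s) failed numeric parsing: {lines}",
            [(i, "<row>", None, msg) for i, msg in parse_failures],
        )

    panelists = replicates = None
    ppath, rpath = _sidecar(path, "panelists"), _sidecar(path, "replicates")
    if ppath.exists():
        panelists = pd.read_csv(ppath, sep=schema.delimiter)
    if rpath.exists():
        replicates = pd.read_csv(rpath, sep=schema.delimiter)

    return PanelDataset(
        records=records,
        attribute_names=attribute_names,
        compound_names=compound_names,
        panelist_ratings=panelists,
        replicate_chem=replicates,
    )


def write_dataset(ds: PanelDataset, path: str | Path, schema: SchemaConfig | None = None) -> None:
    """Write ``ds`` as delimited text so that :func:`read_dataset` round-trips
    it exactly.  Absent volatiles are written as empty fields.  Panelist and
    replicate tables, when present, go to ``<stem>.panelists<ext>`` and
    ``<stem>.replicates<ext>`` sidecars."""
    schema = schema or SchemaConfig()
    path = Path(path)
    df = ds.to_frame()
    df.to_csv(path, sep=schema.delimiter, index=False, float_format=schema.float_format)
    if ds.panelist_ratings is not None:
        ds.panelist_ratings.to_csv(
            _sidecar(path, "panelists"), sep=schema.delimiter, index=False,
            float_format=schema.float_format,
        )
    if ds.replicate_chem is not None:
        ds.replicate_chem.to_csv(
            _sidecar(path, "replicates"), sep=schema.delimiter, index=False,
            float_format=schema.float_format,
        )


def dataset_from_frame(
    df: pd.DataFrame,
    attribute_names: Iterable[str],
    compound_names: Iterable[str],
    panelist_ratings: pd.DataFrame | None = None,
    replicate_chem: pd.DataFrame | None = None,
) -> PanelDataset:
    """Build a validated :class:`PanelDataset` from a wide prefixed frame."""
    records = []
    for i, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                genotype=str(row["genotype"]),
                year=int(row["year"]),
                month=int(row["month"]),
                sensory={a: float(row[SENSORY_PREFIX + a]) for a in attribute_names
                         if pd.notna(row.get(SENSORY_PREFIX + a))},
                ssc=float(row["chem_ssc"]),
                ta=float(row["chem_ta"]),
                ph=float(row["chem_ph"]),
                volatiles={c: float(row[VOLATILE_PREFIX + c]) for c in compound_names
                           if pd.notna(row.get(VOLATILE_PREFIX + c))},
            )
        )
    return PanelDataset(
        records=records,
        attribute_names=list(attribute_names),
        compound_names=list(compound_names),
        panelist_ratings=panelist_ratings,
        replicate_chem=replicate_chem,
    )
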