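"""Per-oocyte model input features with cohort structure.

The feature vector for one oocyte combines four groups plus two clinical
columns:

* mask-specific: aspect ratio, circularity, roundness, solidity of each of
  the three regions (12 columns, tagged by region);
* relative: inner/outer ratios of major axis, minor axis, perimeter and
  area for the pairs ooplasm/PVS, ooplasm/ZP, PVS/ZP (12 columns);
* cohort average: the mean of each relative feature over the oocyte's
  retrieval-cycle cohort, broadcast to every member (12 columns);
* cohort relative: relative feature minus its cohort average, so a negative
  value marks an oocyte below its own cohort's average (12 columns);
* clinical: oocyte age (years) and the number of mature (MII) oocytes in
  the cohort (2 columns).

That makes 48 morphometric + 2 clinical = 50 columns; any named subset can
be dropped to mirror smaller published enumerations.  Only dimensionless
quantities enter — never absolute pixel areas or lengths — because ratios
transfer across magnifications and imaging systems.  A cohort is the set of
oocytes sharing one retrieval cycle (``cycle_id``), not one patient: a
patient can contribute several cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import (
    MEASURES,
    REGION_PAIRS,
    REGIONS,
    MeasurementError,
    relative_features,
    shape_descriptors,
)

__all__ = [
    "FeatureTable",
    "FEATURE_GROUPS",
    "ID_COLUMNS",
    "cohort_average",
    "cohort_relative",
    "assemble_feature_table",
    "feature_schema",
]

logger = logging.getLogger(__name__)

FEATURE_GROUPS = ("ooplasm", "pvs", "zp", "relative", "cohort_avg",
                  "cohort_rel", "clinical")
ID_COLUMNS = ("oocyte_id", "patient_id", "cycle_id", "clinic")
_DESCRIPTORS = ("aspect_ratio", "circularity", "roundness", "solidity")
CLINICAL_FEATURES = ("oocyte_age", "n_mii_oocytes")


def feature_schema() -> dict[str, dict]:
    """Column -> {group, regions} for the full 50-column enumeration.

    ``regions`` lists the oocyte regions a column's value depends on, which
    is what region-wise ablations key on: dropping "zp" must remove the ZP
    descriptors and every relative/cohort column built from a ZP measure.
    """
    schema: dict[str, dict] = {}
    for r in REGIONS:
        for d in _DESCRIPTORS:
            schema[f"{r}_{d}"] = {"group": r, "regions": (r,)}
    rel_cols = [f"{i}_vs_{o}_{m}_ratio" for i, o in REGION_PAIRS for m in MEASURES]
    for i, o in REGION_PAIRS:
        for m in MEASURES:
            col = f"{i}_vs_{o}_{m}_ratio"
            schema[col] = {"group": "relative", "regions": (i, o)}
            schema[f"cohort_avg_{col}"] = {"group": "cohort_avg", "regions": (i, o)}
            schema[f"cohort_rel_{col}"] = {"group": "cohort_rel", "regions": (i, o)}
    for c in CLINICAL_FEATURES:
        schema[c] = {"group": "clinical", "regions": ()}
    assert len(schema) == 50
    return schema


@dataclass
class FeatureTable:
    """Feature matrix plus schema and grouping metadata.

    ``data`` holds the id columns, the ``outcome`` column and every feature
    column; ``schema`` maps each feature column to its group tag and the
    regions it involves.
    """

    data: pd.DataFrame
    schema: dict[str, dict] = field(default_factory=feature_schema)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in self.schema]

    def matrix(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    def columns_of_group(self, group: str) -> list[str]:
        if group in REGIONS:
            return [c for c, m in self.schema.items()
                    if c in self.data.columns and group in m["regions"]]
        if group == "cohort":
            return [c for c, m in self.schema.items()
                    if c in self.data.columns and m["group"] in ("cohort_avg", "cohort_rel")]
        if group not in FEATURE_GROUPS:
            raise KeyError(f"unknown feature group {group!r}")
        return [c for c, m in self.schema.items()
                if c in self.data.columns and m["group"] == group]

    def drop_groups(self, groups) -> "FeatureTable":
        """Table without the named groups.

        Region names ("ooplasm", "pvs", "zp") drop every column involving
        that region, including relative and cohort columns built from it;
        "cohort" drops both cohort_avg and cohort_rel; "clinical" drops the
        two clinical columns.
        """
        drop: set[str] = set()
        for g in groups:
            cols = self.columns_of_group(g)
            if not cols:
                raise KeyError(f"group {g!r} matches no columns")
            drop.update(cols)
        keep = [c for c in self.data.columns if c not in drop]
        if not any(c in self.schema for c in keep):
            raise ValueError("dropping these groups removes every feature")
        schema = {c: m for c, m in self.schema.items() if c not in drop}
        return FeatureTable(data=self.data[keep].copy(), schema=schema)

    def drop_columns(self, columns) -> "FeatureTable":
        """Table without specific named feature columns."""
        missing = [c for c in columns if c not in self.feature_columns]
        if missing:
            raise KeyError(f"unknown feature columns {missing}")
        keep = [c for c in self.data.columns if c not in set(columns)]
        schema = {c: m for c, m in self.schema.items() if c in keep}
        return FeatureTable(data=self.data[keep].copy(), schema=schema)


def cohort_average(table: pd.DataFrame, feature: str,
                   cohort_key: str = "cycle_id") -> pd.Series:
    """Arithmetic mean of *feature* over each cohort, broadcast to members."""
    if table.empty:
        raise ValueError("empty table")
    return table.groupby(cohort_key)[feature].transform("mean")


def cohort_relative(table: pd.DataFrame, feature: str,
                    cohort_key: str = "cycle_id") -> pd.Series:
    """Feature minus its own-cohort average; sums to zero within cohorts."""
    return table[feature] - cohort_average(table, feature, cohort_key)


def _record_row(record) -> dict | None:
    try:
        row: dict = {
            "oocyte_id": record.oocyte_id,
            "patient_id": record.patient_id,
            "cycle_id": record.cycle_id,
            "clinic": record.clinic,
            "outcome": int(record.outcome),
            "oocyte_age": float(record.oocyte_age),
        }
        geoms = record.geometry
        for r in REGIONS:
            d = shape_descriptors(geoms[r])
            row[f"{r}_aspect_ratio"] = d.aspect_ratio
            row[f"{r}_circularity"] = d.circularity
            row[f"{r}_roundness"] = d.roundness
            row[f"{r}_solidity"] = d.solidity
        row.update(relative_features(geoms))
        return row
    except (MeasurementError, KeyError) as exc:
        logger.warning("oocyte %s rejected: %s", record.oocyte_id, exc)
        return None


def assemble_feature_table(records) -> FeatureTable:
    """Build the full feature table from measured oocyte records.

    Records missing any region geometry are rejected with a logged reason.
    The MII-cohort size feature is the number of retained oocytes sharing
    the record's cycle.  Cohort averages and cohort-relative columns are
    computed per cycle after rejection, so every cohort_rel column sums to
    zero within each cohort by construction.
    """
    rows = [r for r in map(_record_row, records) if r is not None]
    if not rows:
        raise ValueError("no measurable oocytes in input")
    df = pd.DataFrame(rows)
    df["n_mii_oocytes"] = df.groupby("cycle_id")["oocyte_id"].transform("count").astype(float)
    rel_cols = [f"{i}_vs_{o}_{m}_ratio" for i, o in REGION_PAIRS for m in MEASURES]
    for col in rel_cols:
        avg = cohort_average(df, col)
        df[f"cohort_avg_{col}"] = avg
        df[f"cohort_rel_{col}"] = df[col] - avg
    table = FeatureTable(data=df)
    feats = table.matrix()
    if feats.isna().any().any():
        bad = feats.columns[feats.isna().any()].tolist()
        raise ValueError(f"missing values in feature columns {bad}")
    return table
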