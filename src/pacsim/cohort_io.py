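"""Cohort schema and CSV input/output.

A cohort is a rectangular table of eyes: 37 pre-treatment clinical and
anatomical predictors, the baseline intraocular pressure (the ``IOP``
feature, mm Hg), an optional post-treatment pressure ``IOP_post``, a
treatment-arm label (``LE`` lens extraction, ``LPI`` laser peripheral
iridotomy, or ``none`` for untreated baselines) and a peripheral
anterior synechiae flag carried as metadata only.  The hypotensive
effect of treatment is ``delta_iop = IOP - IOP_post``.

The 37 predictors cover demographics (age, gender), refraction and
acuity, baseline IOP, lens status, 13 macular choroidal-thickness
points, ocular biometry (axial length, anterior chamber depth, lens
vault), iris curvature and thickness, and anterior-chamber-angle
metrics from AS-OCT (AOD500/750 and TISA500/750 in two sectors) plus
gonioscopic Shaffer grades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd
import yaml

Kind = Literal["continuous", "binary", "ordinal"]

ID_COLUMN = "patient_id"
ARM_COLUMN = "arm"
IOP_POST_COLUMN = "IOP_post"
PAS_COLUMN = "PAS_present"
ARMS = ("LE", "LPI", "none")

#: gender coding used throughout the package (the short indicator's
#: gender coefficient is only meaningful under a fixed convention)
GENDER_MALE = 0
GENDER_FEMALE = 1


@dataclass(frozen=True)
class FeatureSpec:
    """One predictor: name, unit, measurement kind and plausible range.

    ``levels`` enumerates the admissible values for binary and ordinal
    features (e.g. Shaffer grades 0-4); it is ``None`` for continuous
    features, whose plausibility is judged against ``[lo, hi]``.
    """

    name: str
    unit: str
    kind: Kind
    lo: float
    hi: float
    levels: tuple[float, ...] | None = None

    def check(self, value: float) -> str | None:
        """Return a violation message for ``value``, or ``None`` if ok."""
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return "missing value"
        if self.levels is not None:
            if float(value) not in self.levels:
                lo, hi = min(self.levels), max(self.levels)
                return f"value {value!r} outside enumerated levels {lo:g}-{hi:g}"
            return None
        if not (self.lo <= float(value) <= self.hi):
            return f"value {value!r} outside plausible range [{self.lo:g}, {self.hi:g}]"
        return None


class SchemaError(ValueError):
    """A cohort file does not match the feature schema."""


class CohortParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of feature descriptors with unique names."""

    features: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names: {dupes}")
        if not names:
            raise SchemaError("schema must contain at least one feature")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[FeatureSpec]:
        return iter(self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def to_yaml(self, path: str | Path) -> None:
        payload = [
            {
                "name": f.name,
                "unit": f.unit,
                "kind": f.kind,
                "lo": f.lo,
                "hi": f.hi,
                "levels": list(f.levels) if f.levels is not None else None,
            }
            for f in self.features
        ]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        payload = yaml.safe_load(Path(path).read_text())
        feats = tuple(
            FeatureSpec(
                name=d["name"],
                unit=d["unit"],
                kind=d["kind"],
                lo=float(d["lo"]),
                hi=float(d["hi"]),
                levels=tuple(d["levels"]) if d.get("levels") else None,
            )
            for d in payload
        )
        return cls(feats)


def _ct_specs() -> list[FeatureSpec]:
    # 13 macular choroidal-thickness sampling points; stored as generic
    # correlated predictors (no spatial semantics attached).
    return [
        FeatureSpec(f"CT_{i}", "um", "continuous", 50.0, 600.0) for i in range(1, 14)
    ]


def default_schema() -> FeatureSchema:
    """The canonical 37-feature pre-treatment schema."""
    shaffer = tuple(float(g) for g in range(5))
    feats = [
        FeatureSpec("age", "years", "continuous", 18.0, 100.0),
        FeatureSpec("gender", "code", "binary", 0.0, 1.0, (0.0, 1.0)),
        FeatureSpec("spherical_equivalent", "D", "continuous", -10.0, 10.0),
        FeatureSpec("UCVA", "decimal", "continuous", 0.0, 1.5),
        FeatureSpec("BCVA", "decimal", "continuous", 0.0, 1.5),
        FeatureSpec("IOP", "mm Hg", "continuous", 5.0, 45.0),
        FeatureSpec("cataract_present", "code", "binary", 0.0, 1.0, (0.0, 1.0)),
        *_ct_specs(),
        FeatureSpec("AL", "mm", "continuous", 19.0, 28.0),
        FeatureSpec("ACD", "mm", "continuous", 1.2, 4.5),
        FeatureSpec("LV", "mm", "continuous", -0.2, 1.8),
        FeatureSpec("ICurv_nasal", "mm", "continuous", 0.0, 0.9),
        FeatureSpec("ICurv_temporal", "mm", "continuous", 0.0, 0.9),
        FeatureSpec("IT750_nasal", "mm", "continuous", 0.15, 0.8),
        FeatureSpec("IT750_temporal", "mm", "continuous", 0.15, 0.8),
        FeatureSpec("AOD500_90", "mm", "continuous", 0.0, 1.0),
        FeatureSpec("AOD750_90", "mm", "continuous", 0.0, 1.0),
        FeatureSpec("TISA500_90", "mm^2", "continuous", 0.0, 0.5),
        FeatureSpec("TISA750_90", "mm^2", "continuous", 0.0, 0.5),
        FeatureSpec("AOD500_270", "mm", "continuous", 0.0, 1.0),
        FeatureSpec("AOD750_270", "mm", "continuous", 0.0, 1.0),
        FeatureSpec("TISA500_270", "mm^2", "continuous", 0.0, 0.5),
        FeatureSpec("TISA750_270", "mm^2", "continuous", 0.0, 0.5),
        FeatureSpec("Shaffer_90", "grade", "ordinal", 0.0, 4.0, shaffer),
        FeatureSpec("Shaffer_270", "grade", "ordinal", 0.0, 4.0, shaffer),
    ]
    schema = FeatureSchema(tuple(feats))
    assert len(schema) == 37
    return schema


#: module-level default, shared by the generator and the pipeline
DEFAULT_SCHEMA = default_schema()


@dataclass
class Cohort:
    """Patients-by-columns table backed by a pandas DataFrame.

    Columns: ``patient_id``, ``arm``, ``PAS_present`` (metadata, never a
    predictor), the 37 schema features, and ``IOP_post`` (NaN where the
    eye is untreated).
    """

    data: pd.DataFrame
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        required = [ID_COLUMN, ARM_COLUMN, *self.schema.names, IOP_POST_COLUMN]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort is missing columns: {missing}")
        if PAS_COLUMN not in self.data.columns:
            self.data = self.data.assign(**{PAS_COLUMN: 0})
        bad_arms = set(self.data[ARM_COLUMN].unique()) - set(ARMS)
        if bad_arms:
            raise SchemaError(f"unknown arm labels: {sorted(bad_arms)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        """The n x 37 predictor block, in schema order."""
        return self.data[self.schema.names]

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def iop_pre(self) -> pd.Series:
        return self.data["IOP"]

    @property
    def iop_post(self) -> pd.Series:
        return self.data[IOP_POST_COLUMN]

    @property
    def delta_iop(self) -> pd.Series:
        """Hypotensive effect, pre minus post; NaN where untreated."""
        return self.iop_pre - self.iop_post

    @property
    def arm(self) -> pd.Series:
        return self.data[ARM_COLUMN]

    @property
    def pas(self) -> pd.Series:
        return self.data[PAS_COLUMN].astype(int)

    def subset(self, mask) -> "Cohort":
        return Cohort(self.data.loc[mask].reset_index(drop=True), self.schema)

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), self.schema)


@dataclass(frozen=True)
class Violation:
    row: int
    column: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def for_column(self, column: str) -> list[Violation]:
        return [v for v in self.violations if v.column == column]


def load_cohort(path: str | Path, schema: FeatureSchema | None = None) -> Cohort:
    """Read a cohort CSV (comma-delimited, '.' decimal, empty cell = missing).

    Raises :class:`SchemaError` naming any absent column and
    :class:`CohortParseError` with the row index of the first
    non-numeric cell in a numeric column.
    """
    schema = schema or DEFAULT_SCHEMA
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    required = [ID_COLUMN, ARM_COLUMN, *schema.names, IOP_POST_COLUMN]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")

    numeric_cols = [*schema.names, IOP_POST_COLUMN]
    if PAS_COLUMN in raw.columns:
        numeric_cols.append(PAS_COLUMN)
    parsed = {ID_COLUMN: raw[ID_COLUMN], ARM_COLUMN: raw[ARM_COLUMN].fillna("none")}
    for col in numeric_cols:
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"non-numeric value {raw[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        parsed[col] = values
    frame = pd.DataFrame(parsed)
    if PAS_COLUMN not in frame.columns:
        frame[PAS_COLUMN] = 0
    return Cohort(frame, schema)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV with canonical numeric formatting (%.6g)."""
    cols = [ID_COLUMN, ARM_COLUMN, PAS_COLUMN, *cohort.schema.names, IOP_POST_COLUMN]
    cohort.data[cols].to_csv(path, index=False, float_format="%.6g")


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Range/enumeration/missingness report; never mutates the cohort."""
    violations: list[Violation] = []
    for col in cohort.schema.names:
        spec = cohort.schema[col]
        for row, value in enumerate(cohort.data[col]):
            msg = spec.check(value)
            if msg is not None:
                violations.append(Violation(row, col, msg))
    post = cohort.data[IOP_POST_COLUMN]
    treated = cohort.data[ARM_COLUMN].isin(("LE", "LPI"))
    for row in np.flatnonzero((treated & post.isna()).to_numpy()):
        violations.append(
            Violation(int(row), IOP_POST_COLUMN, "treated eye lacks IOP_post")
        )
    return ValidationReport(violations)
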