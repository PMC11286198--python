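"""Validated delimited-text I/O and run configuration.

All interchange is plain CSV/TSV (UTF-8).  Every table passing through the
pipeline is validated against a :class:`TableSchema`; validation errors name
the offending row and column so that bad field data is caught at the door
rather than deep inside a model fit.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
import pandas as pd
import yaml


class SchemaError(ValueError):
    """A table failed schema validation."""


class ConfigError(ValueError):
    """A run-configuration document is invalid."""


@dataclass(frozen=True)
class ColumnSpec:
    """Declared semantics of one table column."""

    name: str
    dtype: str  # "str" | "int" | "float"
    required: bool = True
    min_value: float | None = None
    allowed: tuple[str, ...] | None = None


@dataclass(frozen=True)
class TableSchema:
    """Column-level contract for one CSV table."""

    name: str
    columns: tuple[ColumnSpec, ...]

    @property
    def required_names(self) -> list[str]:
        return [c.name for c in self.columns if c.required]

    def validate(self, df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
        missing = [c for c in self.required_names if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{source}: table '{self.name}' is missing required column(s) "
                f"{missing}"
            )
        out = df.copy()
        for spec in self.columns:
            if spec.name not in out.columns:
                continue
            col = out[spec.name]
            if spec.dtype in ("int", "float"):
                coerced = pd.to_numeric(col, errors="coerce")
                bad = coerced.isna() & col.notna()
                if bad.any():
                    row = int(bad.idxmax())
                    raise SchemaError(
                        f"{source}: unparseable {spec.dtype} value "
                        f"{col[row]!r} in column '{spec.name}' at row {row}"
                    )
                if spec.dtype == "int":
                    nonint = coerced.notna() & (coerced != coerced.round())
                    if nonint.any():
                        row = int(nonint.idxmax())
                        raise SchemaError(
                            f"{source}: non-integer value {col[row]!r} in "
                            f"column '{spec.name}' at row {row}"
                        )
                    coerced = coerced.astype("Int64")
                if spec.min_value is not None:
                    low = coerced.notna() & (coerced < spec.min_value)
                    if low.any():
                        row = int(low.idxmax())
                        raise SchemaError(
                            f"{source}: value {coerced[row]} below minimum "
                            f"{spec.min_value} in column '{spec.name}' at row "
                            f"{row}"
                        )
                out[spec.name] = coerced
            else:
                out[spec.name] = col.astype("string").astype(object)
                if spec.allowed is not None:
                    ok = out[spec.name].isin(spec.allowed) | col.isna()
                    if not ok.all():
                        row = int((~ok).idxmax())
                        raise SchemaError(
                            f"{source}: value {out[spec.name][row]!r} not in "
                            f"allowed set {spec.allowed} in column "
                            f"'{spec.name}' at row {row}"
                        )
        return out


SUGARS = ("fructose", "glucose", "sucrose")
FLOWER_UNITS = ("flower", "capitulum", "inflorescence")
SEXES = ("female", "male")

SCHEMAS: dict[str, TableSchema] = {
    "interactions": TableSchema(
        "interactions",
        (
            ColumnSpec("site", "str"),
            ColumnSpec("bee_species", "str"),
            ColumnSpec("plant_species", "str"),
            ColumnSpec("count", "int", min_value=1),
        ),
    ),
    "specimens": TableSchema(
        "specimens",
        (
            ColumnSpec("specimen", "str"),
            ColumnSpec("species", "str"),
            ColumnSpec("family", "str"),
            ColumnSpec("sex", "str", allowed=SEXES),
            ColumnSpec("length_mm", "float", min_value=1e-9),
        ),
    ),
    "nectar": TableSchema(
        "nectar",
        (
            ColumnSpec("species", "str"),
            ColumnSpec("sugar", "str", allowed=SUGARS),
            ColumnSpec("mass_mg_per_flower", "float", min_value=0.0),
        ),
    ),
    "pollen": TableSchema(
        "pollen",
        (
            ColumnSpec("species", "str"),
            ColumnSpec("mass_mg_per_flower", "float", min_value=0.0),
        ),
    ),
    "calorimetry": TableSchema(
        "calorimetry",
        (
            ColumnSpec("species", "str"),
            ColumnSpec("cal_per_mg", "float", min_value=1e-12),
        ),
    ),
    "taxonomy": TableSchema(
        "taxonomy",
        (
            ColumnSpec("species", "str"),
            ColumnSpec("genus", "str"),
            ColumnSpec("family", "str"),
            ColumnSpec("origin", "str", required=False),
            ColumnSpec("flower_unit", "str", allowed=FLOWER_UNITS),
        ),
    ),
    "transects": TableSchema(
        "transects",
        (
            ColumnSpec("land_class", "str"),
            ColumnSpec("transect_id", "str"),
            ColumnSpec("species", "str"),
            ColumnSpec("count", "int", min_value=0),
            ColumnSpec("length_m", "float", min_value=1e-9),
            ColumnSpec("width_m", "float", min_value=1e-9),
        ),
    ),
    "density": TableSchema(
        "density",
        (
            ColumnSpec("land_class", "str"),
            ColumnSpec("species", "str"),
            ColumnSpec("density_per_m2", "float", min_value=0.0),
            ColumnSpec("unit", "str", required=False, allowed=FLOWER_UNITS),
            ColumnSpec("provenance", "str", required=False),
        ),
    ),
    "composition": TableSchema(
        "composition",
        (
            ColumnSpec("site", "str"),
            ColumnSpec("patch_area_ha", "float", min_value=0.0),
            ColumnSpec("land_class", "str"),
            ColumnSpec("buffer_area_m2", "float", min_value=0.0),
        ),
    ),
    "effort": TableSchema(
        "effort",
        (
            ColumnSpec("site", "str"),
            ColumnSpec("effort_h", "float", min_value=1e-9),
        ),
    ),
    "abundance": TableSchema(
        "abundance",
        (
            ColumnSpec("site", "str"),
            ColumnSpec("bee_species", "str"),
            ColumnSpec("count", "int", min_value=0),
        ),
    ),
}


def read_table(path: str | os.PathLike, schema: TableSchema | str) -> pd.DataFrame:
    """Read a comma- or tab-separated table and validate it against *schema*."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= max(1, first.count(",")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    return schema.validate(df, source=str(path))


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a table as CSV, deterministically (fixed float formatting)."""
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


# ---------------------------------------------------------------------------
# Run configuration


#: Heats of combustion (kcal/mol) and molecular weights (g/mol) for the three
#: dominant nectar sugars.  Their ratio gives energy content in cal/mg.
#: These defaults come from standard combustion tables and may be overridden
#: in the run configuration.
DEFAULT_SUGAR_CONSTANTS: dict[str, dict[str, float]] = {
    "fructose": {"heat_of_combustion_kcal_mol": 675.6, "molecular_weight_g_mol": 180.16},
    "glucose": {"heat_of_combustion_kcal_mol": 669.9, "molecular_weight_g_mol": 180.16},
    "sucrose": {"heat_of_combustion_kcal_mol": 1349.6, "molecular_weight_g_mol": 342.30},
}

#: Mean pollen calorific content (cal/mg) across calorimetry species; used
#: when no calorimetry table is supplied.
DEFAULT_POLLEN_CAL_PER_MG = 4.11


@dataclass
class RunConfig:
    """Structured configuration for a full pipeline run.

    ``paths`` maps table names (keys of :data:`SCHEMAS`) to CSV locations.
    Unknown keys in a config document are rejected outright.
    """

    paths: dict[str, str] = field(default_factory=dict)
    sugar_constants: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUGAR_CONSTANTS.items()}
    )
    pollen_cal_per_mg: float = DEFAULT_POLLEN_CAL_PER_MG
    buffer_radius_m: float = 1000.0
    patch_class: str = "woodland"
    matrix_classes: tuple[str, ...] = ("woodland", "cleared", "pine")
    impute_genus: bool = True
    impute_family: bool = True
    literature_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    families: tuple[str, ...] = ("nb2", "poisson")
    zero_inflation: tuple[bool, ...] = (False, True)
    aicc_window: float = 2.0
    vif_threshold: float = 3.0
    n_quad: int = 15
    n_restarts: int = 3
    seed: int = 0

    def validate(self) -> "RunConfig":
        for key, p in self.paths.items():
            if key not in SCHEMAS:
                raise ConfigError(f"unknown table name in paths: {key!r}")
            if not os.path.exists(p):
                raise ConfigError(f"declared path for {key!r} does not exist: {p}")
        for sugar, consts in self.sugar_constants.items():
            for cname, val in consts.items():
                if val <= 0:
                    raise ConfigError(
                        f"sugar constant {sugar}.{cname} must be positive, got {val}"
                    )
        if self.pollen_cal_per_mg <= 0:
            raise ConfigError("pollen_cal_per_mg must be positive")
        if self.buffer_radius_m <= 0:
            raise ConfigError("buffer_radius_m must be positive")
        if self.aicc_window <= 0:
            raise ConfigError("aicc_window must be positive")
        return self

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
        for tup in ("matrix_classes", "families", "zero_inflation"):
            if tup in doc and isinstance(doc[tup], list):
                doc[tup] = tuple(doc[tup])
        cfg = cls(**doc)
        return cfg

    def to_yaml(self, path: str | os.PathLike) -> None:
        doc = dataclasses.asdict(self)
        for tup in ("matrix_classes", "families", "zero_inflation"):
            doc[tup] = list(doc[tup])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
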