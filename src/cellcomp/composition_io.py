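"""Data model and I/O for replicate measurement tables and medium recipes.

The common currency of the package is the :class:`ConditionDataset`: a tidy
table of (condition, replicate, analyte, value, units) rows, one row per
replicate measurement. Metal quotas are in μg/g dry weight, macromolecular
fractions in mg/g dry weight, and elemental analyses in % of dry weight.

Published tables usually print mean ± sample SD rather than raw replicates;
:func:`expand_mean_sd` deterministically expands such summaries into three
pseudo-replicates (m, m−s, m+s) whose mean and n−1 standard deviation
reproduce the printed values exactly, so printed tables can drive every
downstream computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .chem import FormulaError, parse_chemical_formula

__all__ = [
    "VALID_UNITS",
    "Measurement",
    "ConditionDataset",
    "MediumComponent",
    "MediumRecipe",
    "SchemaError",
    "IntegrityError",
    "load_samples",
    "write_samples",
    "load_medium_recipe",
    "summarize",
    "expand_mean_sd",
]

#: Recognised measurement units (per spec of the input tables).
VALID_UNITS = frozenset({"ug_per_g_dw", "percent_dw", "mg_per_g_dw"})

_REQUIRED_COLUMNS = ("condition", "replicate", "analyte", "value", "units")


class SchemaError(ValueError):
    """A table or recipe file does not match the expected schema."""


class IntegrityError(ValueError):
    """Rows violate dataset invariants (duplicates, negative values...)."""


@dataclass(frozen=True)
class Measurement:
    """One replicate measurement of one analyte under one condition."""

    condition: str
    replicate: int
    analyte: str
    value: float
    units: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise IntegrityError(
                f"negative value {self.value} for {self.analyte!r} "
                f"({self.condition!r}, replicate {self.replicate})"
            )
        if self.units not in VALID_UNITS:
            raise SchemaError(f"unknown units {self.units!r}; expected one of {sorted(VALID_UNITS)}")
        if self.replicate < 1:
            raise IntegrityError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass
class ConditionDataset:
    """Tidy container of replicate measurements across growth conditions."""

    measurements: list[Measurement]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        units_by_analyte: dict[str, str] = {}
        for m in self.measurements:
            key = (m.condition, m.replicate, m.analyte)
            if key in seen:
                raise IntegrityError(f"duplicate (condition, replicate, analyte) = {key}")
            seen.add(key)
            prev = units_by_analyte.setdefault(m.analyte, m.units)
            if prev != m.units:
                raise IntegrityError(
                    f"inconsistent units for analyte {m.analyte!r}: {prev!r} vs {m.units!r}"
                )

    @property
    def conditions(self) -> list[str]:
        return sorted({m.condition for m in self.measurements})

    @property
    def analytes(self) -> list[str]:
        return sorted({m.analyte for m in self.measurements})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.condition, m.replicate, m.analyte, m.value, m.units) for m in self.measurements],
            columns=list(_REQUIRED_COLUMNS),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "ConditionDataset":
        measurements = [
            Measurement(str(r.condition), int(r.replicate), str(r.analyte), float(r.value), str(r.units))
            for r in df.itertuples(index=False)
        ]
        return cls(measurements, metadata or {})

    def values(self, condition: str, analyte: str) -> list[float]:
        """Replicate values for one (condition, analyte), sorted by replicate."""
        rows = [m for m in self.measurements if m.condition == condition and m.analyte == analyte]
        return [m.value for m in sorted(rows, key=lambda m: m.replicate)]

    def subset(self, conditions: list[str] | None = None, analytes: list[str] | None = None) -> "ConditionDataset":
        ms = [
            m
            for m in self.measurements
            if (conditions is None or m.condition in conditions)
            and (analytes is None or m.analyte in analytes)
        ]
        return ConditionDataset(ms, dict(self.metadata))

    def merge(self, other: "ConditionDataset") -> "ConditionDataset":
        return ConditionDataset(self.measurements + other.measurements, {**self.metadata, **other.metadata})


def _clean_numeric(x) -> float:
    """Parse a table cell to float, stripping thousands separators ("1,970")."""
    if isinstance(x, str):
        x = x.replace(",", "").strip()
    return float(x)


def load_samples(path: str | Path, schema: dict[str, str] | None = None) -> ConditionDataset:
    """Read a CSV/TSV replicate table into a validated :class:`ConditionDataset`.

    Parameters
    ----------
    path:
        CSV or TSV file with a header row. The delimiter is sniffed from
        the extension (``.tsv`` → tab) with a fallback sniff on content.
    schema:
        Optional mapping from required column names (condition, replicate,
        analyte, value, units) to the actual column names in the file.

    Raises
    ------
    SchemaError
        If a required column cannot be resolved.
    IntegrityError
        If rows are duplicated, negative, or carry inconsistent units.
        Unparseable numeric cells are reported with their row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    if df.shape[1] == 1 and sep == ",":  # tab-delimited file with .csv extension
        df = pd.read_csv(path, sep="\t", dtype=str, skipinitialspace=True)

    colmap = {c: c for c in _REQUIRED_COLUMNS}
    if schema:
        colmap.update(schema)
    missing = [want for want, have in colmap.items() if have not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path.name}; found {list(df.columns)}")
    df = df.rename(columns={have: want for want, have in colmap.items()})

    bad_rows: list[str] = []
    measurements: list[Measurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            measurements.append(
                Measurement(
                    condition=str(row.condition).strip(),
                    replicate=int(_clean_numeric(row.replicate)),
                    analyte=str(row.analyte).strip(),
                    value=_clean_numeric(row.value),
                    units=str(row.units).strip(),
                )
            )
        except (ValueError, TypeError) as e:
            if isinstance(e, (IntegrityError, SchemaError)):
                raise
            bad_rows.append(f"line {i}: {e}")
    if bad_rows:
        raise IntegrityError("unparseable rows:\n" + "\n".join(bad_rows))
    return ConditionDataset(measurements, {"source": str(path)})


def write_samples(ds: ConditionDataset, path: str | Path) -> None:
    """Write a dataset back to CSV/TSV (inverse of :func:`load_samples`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    ds.to_frame().to_csv(path, sep=sep, index=False)


def summarize(ds: ConditionDataset) -> pd.DataFrame:
    """Per (condition, analyte) mean, sample SD (n−1 denominator), and n.

    Groups with a single replicate report ``sd = NaN`` (undefined rather
    than zero) so that downstream consumers see them flagged.
    """
    df = ds.to_frame()
    out = (
        df.groupby(["condition", "analyte", "units"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out[["condition", "analyte", "mean", "sd", "n", "units"]]


def expand_mean_sd(
    condition: str, analyte: str, mean: float, sd: float, units: str
) -> list[Measurement]:
    """Expand a printed mean ± sample SD into three pseudo-replicates.

    The symmetric triple (m, m−s, m+s) has mean m and sample standard
    deviation exactly s, so summarize() round-trips the printed numbers.
    """
    if sd < 0:
        raise IntegrityError(f"negative SD {sd} for {analyte!r}")
    values = [mean, mean - sd, mean + sd]
    if min(values) < 0:
        raise IntegrityError(
            f"mean-SD expansion of {analyte!r} ({mean}±{sd}) produces a negative replicate"
        )
    return [Measurement(condition, i + 1, analyte, v, units) for i, v in enumerate(values)]


# ---------------------------------------------------------------------------
# Medium recipes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MediumComponent:
    """One chemical component of a culture medium.

    Exactly one concentration specification must be present: either a
    stock solution (``stock_mM``) dosed into the final medium
    (``dose_mL_per_L``), or a direct final concentration (``final_uM``).
    ``supplement`` marks components added post-autoclave (e.g. in the
    anaerobic glove box), which medium-element accounting can exclude.
    """

    name: str
    formula: str
    stock_mM: float | None = None
    dose_mL_per_L: float | None = None
    final_uM: float | None = None
    supplement: bool = False

    def __post_init__(self) -> None:
        has_stock = self.stock_mM is not None or self.dose_mL_per_L is not None
        has_final = self.final_uM is not None
        if has_stock and has_final:
            raise SchemaError(f"component {self.name!r}: give stock+dose or final_uM, not both")
        if has_stock and (self.stock_mM is None or self.dose_mL_per_L is None):
            raise SchemaError(f"component {self.name!r}: stock_mM and dose_mL_per_L required together")
        if not has_stock and not has_final:
            raise SchemaError(f"component {self.name!r}: no concentration given")
        for label, v in (("stock_mM", self.stock_mM), ("dose_mL_per_L", self.dose_mL_per_L), ("final_uM", self.final_uM)):
            if v is not None and v <= 0:
                raise SchemaError(f"component {self.name!r}: {label} must be > 0, got {v}")
        parse_chemical_formula(self.formula)  # raises FormulaError if malformed

    @property
    def final_umol_per_L(self) -> float:
        """μmol of the component per litre of final medium."""
        if self.final_uM is not None:
            return self.final_uM
        return self.stock_mM * self.dose_mL_per_L  # mM * mL/L = μmol/L

    @property
    def element_counts(self) -> dict[str, int]:
        return parse_chemical_formula(self.formula)


@dataclass
class MediumRecipe:
    """A named culture medium: a list of chemical components."""

    name: str
    components: list[MediumComponent]

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate component name(s) in recipe {self.name!r}: {sorted(dupes)}")


def load_medium_recipe(path: str | Path) -> MediumRecipe:
    """Load a YAML or JSON medium recipe.

    Expected document shape::

        name: Geobacter medium
        components:
          - name: ferrous sulfate
            formula: FeSO4·7H2O
            stock_mM: 0.36
            dose_mL_per_L: 10
          - name: ferrous chloride
            formula: FeCl2·4H2O
            final_uM: 20
            supplement: true
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or "components" not in doc:
        raise SchemaError(f"recipe {path.name} must be a mapping with a 'components' list")
    components = []
    for entry in doc["components"]:
        if not isinstance(entry, dict) or "formula" not in entry:
            raise SchemaError(f"recipe {path.name}: each component needs at least a 'formula'")
        try:
            components.append(
                MediumComponent(
                    name=str(entry.get("name", entry["formula"])),
                    formula=str(entry["formula"]),
                    stock_mM=None if entry.get("stock_mM") is None else float(entry["stock_mM"]),
                    dose_mL_per_L=None if entry.get("dose_mL_per_L") is None else float(entry["dose_mL_per_L"]),
                    final_uM=None if entry.get("final_uM") is None else float(entry["final_uM"]),
                    supplement=bool(entry.get("supplement", False)),
                )
            )
        except FormulaError as e:
            raise FormulaError(f"recipe {path.name}, component {entry.get('name', '?')!r}: {e}") from e
    return MediumRecipe(name=str(doc.get("name", path.stem)), components=components)
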