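"""Synthetic replicate generator with the study's statistical structure.

Real composition assays yield a handful of replicate measurements per
growth condition; published tables compress them to mean ± sample SD.
This module regenerates replicate-level data from such summaries: each
(condition, analyte) cell is drawn i.i.d. Gaussian around the configured
mean with the configured SD, truncated at zero by resampling (contents
and mass fractions cannot be negative).

Elemental analytes are special-cased to mirror the measurement process:
C, H, N and ash are drawn, and O is derived by difference so every
synthetic replicate closes to 100% exactly — the same convention the
combustion assay uses. The generator reproduces the published means and
SDs, not the (unpublished) replicate counts or between-analyte
correlations.

The bundled default study covers four growth conditions — Geobacter
sulfurreducens on a poised electrode or on fumarate, and E. coli in
Geobacter medium or in M9 — with iron quotas, macromolecular fractions
and CHN/ash elemental analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .composition_io import ConditionDataset, Measurement

__all__ = [
    "AnalyteSpec",
    "StudySpec",
    "GeneratorError",
    "CONDITIONS",
    "default_study_spec",
    "generate_study",
    "generate_condition",
    "load_study_spec",
]

#: Condition labels of the default study design.
CONDITIONS = ("Gsulf-electrode", "Gsulf-fumarate", "Ecoli-Gmedium", "Ecoli-M9")

#: Analytes drawn jointly with closure to 100% (O derived by difference).
_ELEMENTAL = ("C", "H", "N", "ash")

_MAX_RESAMPLE_ROUNDS = 1000


class GeneratorError(ValueError):
    """Raised for invalid study specs or infeasible noise parameters."""


@dataclass(frozen=True)
class AnalyteSpec:
    """Noise parameters for one analyte: per-condition (mean, SD) pairs."""

    analyte: str
    units: str
    by_condition: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for cond, (mean, sd) in self.by_condition.items():
            if mean < 0 or sd < 0:
                raise GeneratorError(f"{self.analyte}/{cond}: mean and SD must be >= 0 (got {mean}, {sd})")


@dataclass
class StudySpec:
    """Design of a synthetic study: conditions × analytes × noise model."""

    conditions: tuple[str, ...]
    analytes: list[AnalyteSpec]
    n_replicates: int = 3
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_replicates < 0:
            raise GeneratorError(f"n_replicates must be >= 0, got {self.n_replicates}")
        known = set(self.conditions)
        for a in self.analytes:
            unknown = set(a.by_condition) - known
            if unknown:
                raise GeneratorError(f"analyte {a.analyte!r} references unknown condition(s) {sorted(unknown)}")

    def analyte(self, name: str) -> AnalyteSpec:
        for a in self.analytes:
            if a.analyte == name:
                return a
        raise KeyError(name)


def default_study_spec() -> StudySpec:
    """The four-condition study design with its published means and SDs.

    Iron quotas (μg/g dry weight) cover all four conditions; the
    macromolecular fractions (mg/g) and elemental analyses (% dry
    weight) cover the three conditions they were assayed in. The O entry
    records the reported summary for completeness; generated O
    replicates are derived by difference, not drawn from it.
    """
    E, F, G, M = CONDITIONS

    def spec(analyte: str, units: str, **cells: tuple[float, float]) -> AnalyteSpec:
        key = {"electrode": E, "fumarate": F, "gmedium": G, "m9": M}
        return AnalyteSpec(analyte, units, {key[k]: v for k, v in cells.items()})

    return StudySpec(
        conditions=CONDITIONS,
        analytes=[
            spec("Fe", "ug_per_g_dw",
                 electrode=(1970, 226), fumarate=(1960, 229), gmedium=(430, 90), m9=(130, 50)),
            spec("protein", "mg_per_g_dw",
                 electrode=(215, 7), fumarate=(262, 56), m9=(284, 15)),
            spec("lipid", "mg_per_g_dw",
                 electrode=(323, 45), fumarate=(321, 35), m9=(243, 36)),
            spec("carbohydrate", "mg_per_g_dw",
                 electrode=(193, 11), fumarate=(87, 24), m9=(68, 19)),
            spec("C", "percent_dw",
                 electrode=(47.0, 1.1), fumarate=(46.8, 1.8), m9=(46.9, 0.7)),
            spec("H", "percent_dw",
                 electrode=(7.2, 0.6), fumarate=(7.4, 0.1), m9=(7.4, 1.0)),
            spec("N", "percent_dw",
                 electrode=(9.5, 0.2), fumarate=(8.3, 0.3), m9=(12.5, 0.0)),
            spec("O", "percent_dw",
                 electrode=(26.4, 3.3), fumarate=(28.6, 3.9), m9=(24.8, 2.0)),
            spec("ash", "percent_dw",
                 electrode=(9.9, 3.0), fumarate=(9.0, 3.3), m9=(8.4, 1.3)),
        ],
        metadata={"design": "G. sulfurreducens electrode/fumarate vs E. coli G-medium/M9"},
    )


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """n i.i.d. Gaussian(mean, sd) draws truncated at 0 by resampling."""
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, float(mean))
    values = rng.normal(mean, sd, size=n)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = values < 0
        if not bad.any():
            return values
        values[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise GeneratorError(
        f"truncation at 0 infeasible for mean={mean}, sd={sd}: resampling does not converge"
    )


def _draw_elemental(
    rng: np.random.Generator, params: dict[str, tuple[float, float]], n: int
) -> dict[str, np.ndarray]:
    """Draw C, H, N, ash replicates and derive O by difference.

    A replicate is resampled whole if any component is negative or the
    four components exceed 100% (which would make O negative).
    """
    if n == 0:
        return {el: np.empty(0) for el in (*_ELEMENTAL, "O")}
    draws = {el: rng.normal(*params[el], size=n) if params[el][1] > 0 else np.full(n, params[el][0])
             for el in _ELEMENTAL}
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        total = sum(draws.values())
        bad = (total > 100) | np.any([v < 0 for v in draws.values()], axis=0)
        if not bad.any():
            break
        k = int(bad.sum())
        for el in _ELEMENTAL:
            mean, sd = params[el]
            if sd > 0:
                draws[el][bad] = rng.normal(mean, sd, size=k)
    else:
        raise GeneratorError(f"elemental closure infeasible for parameters {params}")
    draws["O"] = 100.0 - sum(draws[el] for el in _ELEMENTAL)
    return draws


def generate_condition(
    spec: StudySpec, condition: str, n: int | None = None, seed: int | None = None
) -> ConditionDataset:
    """Generate n replicates of every analyte for one condition.

    Deterministic for a fixed (spec, n, seed); n defaults to the spec's
    replicate count. n = 0 yields a valid empty dataset.
    """
    if condition not in spec.conditions:
        raise KeyError(f"unknown condition {condition!r}; spec has {list(spec.conditions)}")
    n = spec.n_replicates if n is None else n
    rng = np.random.default_rng(seed)
    measurements: list[Measurement] = []

    elemental = {a.analyte: a for a in spec.analytes if a.analyte in _ELEMENTAL and condition in a.by_condition}
    if elemental:
        missing = set(_ELEMENTAL) - set(elemental)
        if missing:
            raise GeneratorError(
                f"condition {condition!r}: elemental closure needs C, H, N and ash; missing {sorted(missing)}"
            )
        params = {el: elemental[el].by_condition[condition] for el in _ELEMENTAL}
        draws = _draw_elemental(rng, params, n)
        for el in (*_ELEMENTAL, "O"):
            for rep in range(n):
                measurements.append(Measurement(condition, rep + 1, el, float(draws[el][rep]), "percent_dw"))

    for a in spec.analytes:
        if condition not in a.by_condition:
            continue
        if a.analyte in _ELEMENTAL or (a.analyte == "O" and elemental):
            continue  # covered by the closure draw above
        values = _draw_truncated(rng, *a.by_condition[condition], n)
        for rep in range(n):
            measurements.append(Measurement(condition, rep + 1, a.analyte, float(values[rep]), a.units))

    return ConditionDataset(measurements, {"condition": condition, "seed": seed, "n": n})


def generate_study(spec: StudySpec, seed: int) -> ConditionDataset:
    """Generate the full study: every condition, every covered analyte.

    Each condition gets an independent substream spawned from the seed,
    so regenerating one condition does not perturb the others.
    """
    child_seeds = np.random.SeedSequence(seed).spawn(len(spec.conditions))
    ds = ConditionDataset([], {"seed": seed})
    for condition, child in zip(spec.conditions, child_seeds):
        cond_ds = generate_condition(spec, condition, spec.n_replicates, seed=np.random.default_rng(child).integers(2**31))
        ds = ds.merge(cond_ds)
    return ds


def load_study_spec(path: str | Path) -> StudySpec:
    """Load a StudySpec from a YAML document.

    Shape::

        conditions: [A, B]
        n_replicates: 3
        analytes:
          - analyte: Fe
            units: ug_per_g_dw
            by_condition: {A: [1970, 226], B: [130, 50]}
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    analytes = [
        AnalyteSpec(
            analyte=str(a["analyte"]),
            units=str(a["units"]),
            by_condition={str(c): (float(v[0]), float(v[1])) for c, v in a["by_condition"].items()},
        )
        for a in doc["analytes"]
    ]
    return StudySpec(
        conditions=tuple(doc["conditions"]),
        analytes=analytes,
        n_replicates=int(doc.get("n_replicates", 3)),
        metadata=doc.get("metadata", {}),
    )
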