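"""Cohort containers, validation and on-disk formats.

A :class:`Cohort` is a samples x variables numeric matrix with a binary
case/control status vector.  Genotypes are additive-coded counts of the
effect allele (0/1/2); insertion/deletion alleles use the symbols ``I``/``D``
as effect allele.  Missing values are stored as NaN; on disk they are the
empty string or the token ``NA``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_KINDS = ("genotype", "binary", "continuous")
MISSING_TOKENS = ("", "NA")


class CohortError(ValueError):
    """Raised when a cohort or model file violates its contract."""


@dataclass(frozen=True)
class VariableMeta:
    """Description of one cohort column.

    Parameters
    ----------
    name : str
        Column identifier, unique within a cohort.
    kind : {"genotype", "binary", "continuous"}
        Coding of the column.  Genotype columns hold effect-allele counts
        in {0, 1, 2}; binary columns hold {0, 1}.
    effect_allele : str, optional
        Nucleotide or I/D symbol; required iff ``kind == "genotype"``.
    gene_label : str, optional
        Free-text gene annotation.
    """

    name: str
    kind: str
    effect_allele: str | None = None
    gene_label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise CohortError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if (self.kind == "genotype") != (self.effect_allele is not None):
            raise CohortError(
                f"variable {self.name!r}: effect_allele must be given iff kind is genotype"
            )


@dataclass
class Cohort:
    """Case-control cohort: status vector plus numeric variable matrix.

    ``values`` is a float matrix of shape (n_samples, n_variables); missing
    entries are NaN.  ``status`` is 1 for cases (women who developed VTE
    while using combined oral contraceptives) and 0 for controls.
    """

    sample_ids: list[str]
    status: np.ndarray
    schema: list[VariableMeta]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.schema)):
            raise CohortError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.schema)} variables"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise CohortError(f"duplicate sample_id(s): {dupes}")
        if not np.isin(self.status, (0, 1)).all():
            raise CohortError("status values must be 0 (control) or 1 (case)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def var_names(self) -> list[str]:
        return [v.name for v in self.schema]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def case_mask(self) -> np.ndarray:
        return self.status == 1

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    def var_index(self, name: str) -> int:
        try:
            return self.var_names.index(name)
        except ValueError:
            raise CohortError(f"unknown variable {name!r}") from None

    def meta(self, name: str) -> VariableMeta:
        return self.schema[self.var_index(name)]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.var_index(name)]

    def subset(self, sample_ids: Sequence[str]) -> "Cohort":
        """Row subset in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return Cohort(list(sample_ids), self.status[idx], list(self.schema), self.values[idx])

    def copy(self) -> "Cohort":
        return Cohort(list(self.sample_ids), self.status.copy(), list(self.schema), self.values.copy())

    def design_matrix(self, variables: Sequence[str]) -> np.ndarray:
        """(n, 1+k) matrix [1, x1..xk]; raises on missing values."""
        cols = [self.column(v) for v in variables]
        X = np.column_stack([np.ones(self.n_samples)] + cols) if cols else np.ones((self.n_samples, 1))
        if np.isnan(X).any():
            bad = [v for v in variables if np.isnan(self.column(v)).any()]
            raise CohortError(f"design matrix contains missing values in {bad}")
        return X

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.var_names)
        df.insert(0, "status", self.status.astype(int))
        df.insert(0, "sample_id", self.sample_ids)
        return df


# ---------------------------------------------------------------------------
# CSV round-trip


def read_cohort_csv(path: str | os.PathLike, schema: Sequence[VariableMeta]) -> Cohort:
    """Read and validate a cohort CSV (``sample_id,status,<var1>,...``).

    Empty cells and the literal token ``NA`` become missing.  Genotype
    entries must be integers in {0,1,2}, binary entries in {0,1}; a value
    outside the coding raises :class:`CohortError` naming column and row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["sample_id", "status"] + [v.name for v in schema]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise CohortError(f"missing column(s) in {path}: {missing_cols}")

    sample_ids = df["sample_id"].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted(df["sample_id"][df["sample_id"].duplicated()].unique().tolist())
        raise CohortError(f"duplicate sample_id(s): {dupes}")

    try:
        status = df["status"].astype(int).to_numpy()
    except ValueError as exc:
        raise CohortError(f"non-integer status value: {exc}") from None
    if not np.isin(status, (0, 1)).all():
        bad = df.index[~np.isin(status, (0, 1))][0]
        raise CohortError(f"status not in {{0,1}} at row {bad + 2} (sample {sample_ids[bad]})")

    n = len(df)
    values = np.full((n, len(schema)), np.nan)
    for j, meta in enumerate(schema):
        raw = df[meta.name]
        for i, cell in enumerate(raw):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                continue
            try:
                x = float(cell)
            except ValueError:
                raise CohortError(
                    f"column {meta.name!r}, row {i + 2}: non-numeric value {cell!r}"
                ) from None
            values[i, j] = x
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if meta.kind == "genotype" and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            i = int(np.where(~np.isnan(col) & ~np.isin(col, (0.0, 1.0, 2.0)))[0][0])
            raise CohortError(
                f"column {meta.name!r}, row {i + 2}: genotype value {col[i]:g} not in {{0,1,2}}"
            )
        if meta.kind == "binary" and not np.isin(obs, (0.0, 1.0)).all():
            i = int(np.where(~np.isnan(col) & ~np.isin(col, (0.0, 1.0)))[0][0])
            raise CohortError(
                f"column {meta.name!r}, row {i + 2}: binary value {col[i]:g} not in {{0,1}}"
            )
    return Cohort(sample_ids, status, list(schema), values)


def write_cohort_csv(cohort: Cohort, path: str | os.PathLike) -> None:
    """Write a cohort CSV; missing cells are written as ``NA``.

    Genotype and binary entries are written as bare integers so that the
    read/write round-trip is byte-stable.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(["sample_id", "status"] + cohort.var_names) + "\n")
        ints = [m.kind in ("genotype", "binary") for m in cohort.schema]
        for i, sid in enumerate(cohort.sample_ids):
            row = [sid, str(int(cohort.status[i]))]
            for j in range(len(cohort.schema)):
                x = cohort.values[i, j]
                if math.isnan(x):
                    row.append("NA")
                elif ints[j]:
                    row.append(str(int(x)))
                else:
                    row.append(repr(float(x)))
            fh.write(",".join(row) + "\n")


def validate_cohort(cohort: Cohort) -> list[str]:
    """Return a list of contract violations (empty list = valid).

    Flags, besides coding errors: variables missing in every sample and
    variables with no non-missing control value — the latter break hot-deck
    imputation, whose donor pools are drawn from controls.
    """
    report: list[str] = []
    if cohort.n_cases == 0:
        report.append("cohort has no cases")
    if cohort.n_controls == 0:
        report.append("cohort has no controls")
    ctrl = ~cohort.case_mask
    for j, meta in enumerate(cohort.schema):
        col = cohort.values[:, j]
        obs = col[~np.isnan(col)]
        if meta.kind == "genotype" and obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            report.append(f"variable {meta.name!r}: genotype values outside {{0,1,2}}")
        if meta.kind == "binary" and obs.size and not np.isin(obs, (0.0, 1.0)).all():
            report.append(f"variable {meta.name!r}: binary values outside {{0,1}}")
        if np.isnan(col).all():
            report.append(f"variable {meta.name!r}: missing in every sample")
        elif np.isnan(col[ctrl]).all():
            report.append(f"variable {meta.name!r}: no control donor pool (missing in every control)")
    return report


# ---------------------------------------------------------------------------
# Model specifications


@dataclass
class ModelSpec:
    """A named set of predictor variables, optionally with fixed coefficients.

    With ``refit=True`` the coefficients (if any) are ignored by the
    evaluation harness and re-estimated on every training set; with
    ``refit=False`` the stored coefficients are applied as-is and must be
    present for every variable.
    """

    name: str
    variables: list[str]
    coefficients: dict[str, float | None] = field(default_factory=dict)
    se: dict[str, float | None] = field(default_factory=dict)
    selection_frequency: dict[str, float | None] = field(default_factory=dict)
    intercept: float | None = None
    refit: bool = True

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise CohortError(f"model {self.name!r}: duplicate variables")
        if not self.refit:
            missing = [v for v in self.variables if self.coefficients.get(v) is None]
            if missing:
                raise CohortError(
                    f"model {self.name!r}: refit=false requires coefficients; missing for {missing}"
                )

    def coefficient_vector(self) -> np.ndarray:
        return np.array([self.coefficients[v] for v in self.variables], dtype=float)


def write_model_json(model, path: str | os.PathLike) -> None:
    """Serialize a :class:`ModelSpec` (or anything with ``to_model_spec``)."""
    if hasattr(model, "to_model_spec"):
        model = model.to_model_spec()
    payload = {
        "name": model.name,
        "refit": bool(model.refit),
        "intercept": model.intercept,
        "variables": [
            {
                "name": v,
                "coefficient": model.coefficients.get(v),
                "se": model.se.get(v),
                "selection_frequency": model.selection_frequency.get(v),
            }
            for v in model.variables
        ],
    }
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    os.replace(tmp, path)


def read_model_json(path: str | os.PathLike) -> ModelSpec:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        variables = [v["name"] for v in payload["variables"]]
        spec = ModelSpec(
            name=payload["name"],
            variables=variables,
            coefficients={v["name"]: v.get("coefficient") for v in payload["variables"]},
            se={v["name"]: v.get("se") for v in payload["variables"]},
            selection_frequency={
                v["name"]: v.get("selection_frequency") for v in payload["variables"]
            },
            intercept=payload.get("intercept"),
            refit=bool(payload["refit"]),
        )
    except (KeyError, TypeError) as exc:
        raise CohortError(f"malformed model JSON {path}: {exc}") from None
    return spec


# ---------------------------------------------------------------------------
# Optional VCF import


def read_vcf_genotypes(path: str | os.PathLike, effect_alleles: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Convert VCF GT fields to effect-allele counts (samples x variants).

    By default the ALT allele is counted; pass ``effect_alleles`` mapping a
    variant ID to its REF allele to count REF instead.  Half-calls and
    ``./.`` become missing (NaN).  Requires cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for rec in vcf:
        name = rec.ID or f"{rec.CHROM}:{rec.POS}"
        counts = np.full(len(samples), np.nan)
        for i, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                counts[i] = float(sum(1 for a in alleles if a > 0))
        if effect_alleles and effect_alleles.get(name) == rec.REF:
            counts = 2.0 - counts
        data[name] = counts
    return pd.DataFrame(data, index=samples)
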