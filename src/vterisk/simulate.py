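"""Synthetic case-control cohort generation.

Individual-level data for the study this pipeline targets are not public,
so analyses are exercised on simulated cohorts that reproduce its
statistical structure: SNP genotypes under Hardy-Weinberg equilibrium at
stated effect-allele frequencies, clinical covariates from their reported
control distributions, disease status from an additive logistic model with
the reported per-allele odds ratios, and the study's structured
missingness (family history and the two thrombophilia genotypes masked in
a designated control subset).

Sampling is case-control: population individuals are simulated and
accepted by status until the requested numbers of cases and controls are
collected.  For logistic models this retrospective sampling leaves every
coefficient except the intercept identifiable, so the intercept is not a
recovery target.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .cohort import Cohort, CohortError, VariableMeta


@dataclass(frozen=True)
class VariantSpec:
    """A simulated SNP: population effect-allele frequency and true log-OR."""

    name: str
    effect_allele_freq: float
    true_log_or: float = 0.0
    effect_allele: str = "A"
    gene_label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_allele_freq <= 1.0:
            raise CohortError(f"{self.name}: effect_allele_freq must be in [0,1]")


@dataclass(frozen=True)
class ClinicalGenSpec:
    """A simulated clinical covariate.

    Binary covariates are Bernoulli(prevalence); continuous covariates are
    truncated normals (redraw until within [lower, upper]).
    """

    name: str
    kind: str  # "binary" or "continuous"
    true_log_or: float = 0.0
    prevalence: float | None = None
    mean: float | None = None
    sd: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if self.prevalence is None or not 0.0 <= self.prevalence <= 1.0:
                raise CohortError(f"{self.name}: binary covariate needs prevalence in [0,1]")
        elif self.kind == "continuous":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise CohortError(f"{self.name}: continuous covariate needs mean and sd > 0")
            if self.lower is not None and self.upper is not None and self.lower >= self.upper:
                raise CohortError(f"{self.name}: lower bound must be below upper bound")
        else:
            raise CohortError(f"{self.name}: kind must be binary or continuous")


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    true_log_or: dict[str, float]
    baseline_logit: float
    seed: int
    n_cases: int
    n_controls: int
    variants: list[dict] = field(default_factory=list)
    clinicals: list[dict] = field(default_factory=list)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthRecord":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Study panel: the 9 selected SNPs with their printed control effect-allele
# frequencies and per-allele odds ratios, and the 4 clinical risk factors
# with their control-population distributions and per-unit odds ratios.

STUDY_SNPS: tuple[VariantSpec, ...] = (
    VariantSpec("rs6025", 0.02, math.log(6.46), "A", "F5"),
    VariantSpec("rs1799963", 0.01, math.log(5.32), "A", "F2"),
    VariantSpec("rs8176719", 0.41, math.log(1.52), "I", "ABO"),
    VariantSpec("rs2289252", 0.42, math.log(1.34), "T", "F11"),
    VariantSpec("rs1799853", 0.12, math.log(1.54), "T", "CYP2C9"),
    VariantSpec("rs9574", 0.51, math.log(1.25), "G", "PROCR"),
    VariantSpec("rs8176750", 0.07, math.log(0.60), "D", "ABO"),
    VariantSpec("rs4379368", 0.08, math.log(1.35), "T", "SUGCT"),
    VariantSpec("rs710446", 0.43, math.log(1.22), "G", "KNG1"),
)

# SNPs used by published comparison scores but carrying no effect in the
# generator's truth; frequencies are typical European values.
COMPARISON_SNPS: tuple[VariantSpec, ...] = (
    VariantSpec("rs2066865", 0.24, 0.0, "A", "FGG"),
    VariantSpec("rs2036914", 0.47, 0.0, "C", "F11"),
)

STUDY_CLINICALS: tuple[ClinicalGenSpec, ...] = (
    ClinicalGenSpec("age", "continuous", math.log(1.01), mean=31.5, sd=9.0, lower=18.0, upper=51.0),
    ClinicalGenSpec("bmi", "continuous", math.log(1.07), mean=23.0, sd=4.2, lower=17.5, upper=33.5),
    ClinicalGenSpec("smoking", "binary", math.log(1.63), prevalence=0.25),
    ClinicalGenSpec("family_history", "binary", math.log(2.13), prevalence=0.15),
)

STUDY_N_CASES = 794
STUDY_N_CONTROLS = 828

#: Default population baseline log-odds.  Under the default panel the mean
#: linear-predictor offset is about +3.3, so this baseline puts the
#: population case prevalence near 0.3% — the rare-disease regime of VTE
#: among contraceptive users, where the marginal case allele-frequency
#: enrichment approaches exp(log-OR) and reproduces the reported case
#: frequencies (e.g. ~0.09 vs 0.02 for the F5-Leiden-like variant).
DEFAULT_BASELINE_LOGIT = -9.0


def decoy_variants(n_decoys: int = 30, seed: int = 0, freq_range: tuple[float, float] = (0.05, 0.5)) -> list[VariantSpec]:
    """Null SNPs (log-OR 0) standing in for the unnamed remainder of the panel."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, size=n_decoys)
    return [VariantSpec(f"decoy_{i + 1:03d}", float(f), 0.0, "A") for i, f in enumerate(freqs)]


def study_panel(n_decoys: int = 30, include_comparison_snps: bool = True, decoy_seed: int = 0) -> tuple[list[VariantSpec], list[ClinicalGenSpec]]:
    """Default simulation panel: 9 effect SNPs (+2 null comparison SNPs) + decoys, and the 4 clinical factors."""
    variants = list(STUDY_SNPS)
    if include_comparison_snps:
        variants += list(COMPARISON_SNPS)
    variants += decoy_variants(n_decoys, seed=decoy_seed)
    return variants, list(STUDY_CLINICALS)


# ---------------------------------------------------------------------------


def _draw_truncated_normal(rng: np.random.Generator, spec: ClinicalGenSpec, size: int) -> np.ndarray:
    out = rng.normal(spec.mean, spec.sd, size=size)
    lo = -np.inf if spec.lower is None else spec.lower
    hi = np.inf if spec.upper is None else spec.upper
    bad = (out < lo) | (out > hi)
    # redraw out-of-bounds values until all fall inside the brackets
    for _ in range(1000):
        k = int(bad.sum())
        if k == 0:
            break
        out[bad] = rng.normal(spec.mean, spec.sd, size=k)
        bad = (out < lo) | (out > hi)
    else:
        raise CohortError(f"{spec.name}: truncation bounds reject essentially all draws")
    return out


def generate_cohort(
    variants: Sequence[VariantSpec],
    clinicals: Sequence[ClinicalGenSpec],
    n_cases: int = STUDY_N_CASES,
    n_controls: int = STUDY_N_CONTROLS,
    baseline_logit: float = DEFAULT_BASELINE_LOGIT,
    seed: int = 0,
    max_batches: int = 2000,
) -> tuple[Cohort, TruthRecord]:
    """Simulate a case-control cohort under the additive logistic model.

    Genotypes are two independent Bernoulli(effect_allele_freq) allele
    draws (Hardy-Weinberg equilibrium); disease status is Bernoulli on
    ``logistic(baseline_logit + sum(true_log_or * x))``.  Individuals are
    simulated in batches and accepted by status until exactly ``n_cases``
    cases and ``n_controls`` controls are collected.  The same seed always
    yields the identical cohort.
    """
    if n_cases < 1 or n_controls < 1:
        raise CohortError("n_cases and n_controls must be >= 1")
    names = [v.name for v in variants] + [c.name for c in clinicals]
    if len(set(names)) != len(names):
        raise CohortError("duplicate variable names in generator panel")

    rng = np.random.default_rng(seed)
    lor = np.array([v.true_log_or for v in variants] + [c.true_log_or for c in clinicals])

    kept_cases: list[np.ndarray] = []
    kept_ctrls: list[np.ndarray] = []
    got_cases = got_ctrls = 0
    batch = max(1000, n_cases + n_controls)
    for _ in range(max_batches):
        cols = [rng.binomial(2, v.effect_allele_freq, size=batch).astype(float) for v in variants]
        for c in clinicals:
            if c.kind == "binary":
                cols.append(rng.binomial(1, c.prevalence, size=batch).astype(float))
            else:
                cols.append(_draw_truncated_normal(rng, c, batch))
        X = np.column_stack(cols)
        eta = baseline_logit + X @ lor
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        if got_cases < n_cases:
            take = X[y][: n_cases - got_cases]
            kept_cases.append(take)
            got_cases += len(take)
        if got_ctrls < n_controls:
            take = X[~y][: n_controls - got_ctrls]
            kept_ctrls.append(take)
            got_ctrls += len(take)
        if got_cases >= n_cases and got_ctrls >= n_controls:
            break
        # rare-disease regime: grow batches so case accrual stays cheap
        batch = min(2 * batch, 500_000)
    else:
        raise CohortError(
            f"case-control accrual did not finish within {max_batches} batches "
            f"(baseline_logit={baseline_logit} too extreme?)"
        )

    values = np.vstack([np.vstack(kept_cases), np.vstack(kept_ctrls)])
    status = np.concatenate([np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)])
    sample_ids = [f"case_{i + 1:04d}" for i in range(n_cases)] + [
        f"ctrl_{i + 1:04d}" for i in range(n_controls)
    ]
    schema = [
        VariableMeta(v.name, "genotype", v.effect_allele, v.gene_label) for v in variants
    ] + [VariableMeta(c.name, c.kind) for c in clinicals]

    cohort = Cohort(sample_ids, status, schema, values)
    truth = TruthRecord(
        true_log_or={n: float(b) for n, b in zip(names, lor)},
        baseline_logit=baseline_logit,
        seed=seed,
        n_cases=n_cases,
        n_controls=n_controls,
        variants=[asdict(v) for v in variants],
        clinicals=[asdict(c) for c in clinicals],
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Missingness


def apply_missingness(
    cohort: Cohort,
    mcar_rate: float = 0.0,
    structured_masks: Sequence[tuple[Sequence[str], Sequence[str]]] = (),
    seed: int = 0,
) -> Cohort:
    """Return a copy with cells masked to missing.

    Every (sample, variable) cell named by a structured mask becomes
    missing; each remaining cell is additionally missing independently
    with probability ``mcar_rate``.  Status is never masked.
    """
    if not 0.0 <= mcar_rate <= 1.0:
        raise CohortError("mcar_rate must be in [0,1]")
    out = cohort.copy()
    pos = {s: i for i, s in enumerate(out.sample_ids)}
    structured = np.zeros(out.values.shape, dtype=bool)
    for sample_subset, var_list in structured_masks:
        try:
            rows = [pos[s] for s in sample_subset]
        except KeyError as exc:
            raise CohortError(f"structured mask references unknown sample {exc.args[0]!r}") from None
        cols = [out.var_index(v) for v in var_list]
        structured[np.ix_(rows, cols)] = True
    rng = np.random.default_rng(seed)
    mcar = rng.random(out.values.shape) < mcar_rate
    out.values[structured | mcar] = np.nan
    return out


def study_missingness_masks(
    cohort: Cohort, n_masked_controls: int = 523,
    masked_variables: Sequence[str] = ("family_history", "rs6025", "rs1799963"),
) -> list[tuple[list[str], list[str]]]:
    """The study's structured mask: the first ``n_masked_controls`` controls
    lose family history and the two thrombophilia genotypes (the control
    subset recruited through thrombophilia screening, whose values would
    otherwise import an ascertainment bias)."""
    ctrl_ids = [s for s, st in zip(cohort.sample_ids, cohort.status) if st == 0]
    if len(ctrl_ids) < n_masked_controls:
        raise CohortError(
            f"cohort has {len(ctrl_ids)} controls, fewer than {n_masked_controls} to mask"
        )
    present = [v for v in masked_variables if v in cohort.var_names]
    return [(ctrl_ids[:n_masked_controls], present)]
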