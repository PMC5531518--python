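"""Pre-analysis QC and case/control descriptive comparison.

Two pieces: an allele-frequency concordance filter that compares cohort
control allele counts against a user-supplied reference panel with a
two-sided Fisher exact test (variants with p <= alpha are discarded), and
a descriptive table comparing cases to controls with Wilcoxon rank-sum
tests.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, CohortError

log = logging.getLogger(__name__)


@dataclass
class AFComparison:
    variant: str
    cohort_effect: int
    cohort_other: int
    reference_effect: int | None
    reference_other: int | None
    fisher_p: float | None
    keep: bool


@dataclass
class DescriptiveRow:
    variable: str
    kind: str
    case_n: int
    control_n: int
    case_count: int | None
    case_percent: float | None
    control_count: int | None
    control_percent: float | None
    case_mean: float | None
    case_sd: float | None
    case_range: tuple[float, float] | None
    control_mean: float | None
    control_sd: float | None
    control_range: tuple[float, float] | None
    p_value: float


def allele_frequency(cohort: Cohort, variant: str, subset: str = "all") -> tuple[float, int]:
    """Effect-allele frequency and allele count in a subset.

    Missing genotypes contribute to neither numerator nor denominator;
    frequency = (sum of genotypes) / (2 * number of non-missing samples).
    """
    if cohort.meta(variant).kind != "genotype":
        raise CohortError(f"{variant!r} is not a genotype variable")
    col = cohort.column(variant)
    if subset == "cases":
        col = col[cohort.case_mask]
    elif subset == "controls":
        col = col[~cohort.case_mask]
    elif subset != "all":
        raise CohortError(f"unknown subset {subset!r}")
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise CohortError(f"{variant!r}: every genotype missing in subset {subset!r}")
    n_alleles = 2 * obs.size
    return float(obs.sum()) / n_alleles, int(n_alleles)


def fisher_af_filter(
    cohort: Cohort,
    reference: Mapping[str, tuple[int, int]],
    alpha: float = 0.01,
) -> list[AFComparison]:
    """Allele-frequency concordance filter against a reference panel.

    For each genotype variant, builds the 2x2 table of (effect, other)
    allele counts in cohort controls vs the reference and applies the
    two-sided Fisher exact test.  A variant is kept iff p > alpha
    (strictly); p exactly equal to alpha discards.  Variants without a
    reference entry pass with a logged warning and no p-value.
    """
    out: list[AFComparison] = []
    for meta in cohort.schema:
        if meta.kind != "genotype":
            continue
        freq, n_alleles = allele_frequency(cohort, meta.name, "controls")
        eff = int(round(freq * n_alleles))
        oth = n_alleles - eff
        ref = reference.get(meta.name)
        if ref is None:
            log.warning("variant %s absent from reference panel; kept by default", meta.name)
            out.append(AFComparison(meta.name, eff, oth, None, None, None, True))
            continue
        ref_eff, ref_oth = int(ref[0]), int(ref[1])
        if min(ref_eff, ref_oth) < 0:
            raise CohortError(f"{meta.name}: negative reference allele count")
        _, p = stats.fisher_exact([[eff, oth], [ref_eff, ref_oth]], alternative="two-sided")
        out.append(AFComparison(meta.name, eff, oth, ref_eff, ref_oth, float(p), bool(p > alpha)))
    return out


def read_reference_af(path: str | os.PathLike) -> dict[str, tuple[int, int]]:
    """Read a reference allele-count table.

    Native form: CSV with columns ``variant,effect_allele,effect_count,
    other_count``.  A frequency form (``variant,effect_allele,effect_freq,
    n_samples``) is converted by rounding to nearest integer counts over
    2*n_samples alleles.
    """
    df = pd.read_csv(path)
    out: dict[str, tuple[int, int]] = {}
    if {"effect_count", "other_count"} <= set(df.columns):
        for _, r in df.iterrows():
            out[str(r["variant"])] = (int(r["effect_count"]), int(r["other_count"]))
    elif {"effect_freq", "n_samples"} <= set(df.columns):
        for _, r in df.iterrows():
            total = 2 * int(r["n_samples"])
            eff = int(round(float(r["effect_freq"]) * total))
            out[str(r["variant"])] = (eff, total - eff)
    else:
        raise CohortError(
            f"{path}: expected columns effect_count/other_count or effect_freq/n_samples"
        )
    return out


def qc_report(comparisons: Sequence[AFComparison]) -> pd.DataFrame:
    """QC report mirroring the study's supplementary AF-concordance table."""
    rows = []
    for c in comparisons:
        tot = c.cohort_effect + c.cohort_other
        ref_tot = None if c.reference_effect is None else c.reference_effect + c.reference_other
        rows.append(
            {
                "variant": c.variant,
                "cohort_af": c.cohort_effect / tot if tot else np.nan,
                "reference_af": (c.reference_effect / ref_tot) if ref_tot else np.nan,
                "fisher_p": np.nan if c.fisher_p is None else c.fisher_p,
                "kept": c.keep,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Descriptives


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both groups have <= 25 observations and
    the pooled sample is tie-free; otherwise the normal approximation with
    tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CohortError("wilcoxon_rank_sum needs non-empty groups")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0  # rank statistic degenerate: no evidence either way
    tie_free = np.unique(pooled).size == pooled.size
    if max(x.size, y.size) <= 25 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def descriptive_table(cohort: Cohort) -> list[DescriptiveRow]:
    """Per-variable case/control summary with Wilcoxon rank-sum p-values.

    Binary variables report count and percent (over non-missing); continuous
    and genotype variables report mean, SD and observed range.  Percentages
    are always recomputable from count and n.
    """
    rows: list[DescriptiveRow] = []
    case = cohort.case_mask
    for meta in cohort.schema:
        col = cohort.column(meta.name)
        xc = col[case & ~np.isnan(col)]
        xk = col[~case & ~np.isnan(col)]
        if xc.size == 0 or xk.size == 0:
            p = np.nan
        else:
            p = wilcoxon_rank_sum(xc, xk)
        if meta.kind == "binary":
            rows.append(
                DescriptiveRow(
                    meta.name, meta.kind, xc.size, xk.size,
                    int(xc.sum()), 100.0 * xc.mean() if xc.size else None,
                    int(xk.sum()), 100.0 * xk.mean() if xk.size else None,
                    None, None, None, None, None, None, p,
                )
            )
        else:
            rows.append(
                DescriptiveRow(
                    meta.name, meta.kind, xc.size, xk.size,
                    None, None, None, None,
                    float(xc.mean()), float(xc.std(ddof=1)) if xc.size > 1 else None,
                    (float(xc.min()), float(xc.max())) if xc.size else None,
                    float(xk.mean()), float(xk.std(ddof=1)) if xk.size > 1 else None,
                    (float(xk.min()), float(xk.max())) if xk.size else None,
                    p,
                )
            )
    return rows


def descriptive_dataframe(rows: Sequence[DescriptiveRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
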