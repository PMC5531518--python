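"""Rank-based AUC, cross-validated out-of-sample evaluation, and the
published-model comparison harness.

The AUC is the Mann-Whitney statistic: the probability that a randomly
chosen case outranks a randomly chosen control, ties credited 0.5.  Models
are evaluated on the same replicate schedule (seed-for-seed identical
imputations and splits) so AUC differences between models are paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .cohort import Cohort, CohortError, ModelSpec
from .ensemble import fit_logistic, replicate_data
from .resample import replicate_seed

#: Fixed variable sets from the literature and from the study itself.
#: All registry models are refit per training set.
MODEL_REGISTRY: dict[str, list[str]] = {
    # 5-SNP general-VTE genetic score
    "dehaan5": ["rs6025", "rs1799963", "rs8176719", "rs2066865", "rs2036914"],
    # 6-SNP main-effects reduction of the 7-SNP + interactions score
    # (rs514659 tagged by its proxy rs8176719; rs1799810 unavailable)
    "bruzelius6": ["rs6025", "rs1799963", "rs8176719", "rs2289252", "rs710446", "rs2066865"],
    "genetic9": [
        "rs6025", "rs1799963", "rs8176719", "rs2289252", "rs1799853",
        "rs9574", "rs8176750", "rs4379368", "rs710446",
    ],
    "clinical4": ["age", "bmi", "smoking", "family_history"],
}
MODEL_REGISTRY["combined13"] = MODEL_REGISTRY["clinical4"] + MODEL_REGISTRY["genetic9"]


def registry_model(name: str) -> ModelSpec:
    try:
        return ModelSpec(name=name, variables=list(MODEL_REGISTRY[name]), refit=True)
    except KeyError:
        raise CohortError(f"unknown registry model {name!r}; known: {sorted(MODEL_REGISTRY)}") from None


def auc_rank(case_scores: Sequence[float], control_scores: Sequence[float]) -> float:
    """Rank AUC: P(case score > control score) + 0.5 P(equal)."""
    cases = np.asarray(case_scores, dtype=float)
    ctrls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or ctrls.size == 0:
        raise CohortError("auc_rank needs non-empty case and control score sets")
    ranks = rankdata(np.concatenate([cases, ctrls]))
    r1 = ranks[: cases.size].sum()
    return float((r1 - cases.size * (cases.size + 1) / 2.0) / (cases.size * ctrls.size))


@dataclass
class ROCCurve:
    """Ordered ROC points from (0,0) to (1,1); area by the trapezoid rule."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if (np.diff(self.fpr) < -1e-12).any() or (np.diff(self.tpr) < -1e-12).any():
            raise CohortError("ROC coordinates must be non-decreasing")

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))

    @classmethod
    def from_scores(cls, scores: np.ndarray, status: np.ndarray) -> "ROCCurve":
        fpr, tpr, _ = roc_curve(status, scores)
        fpr = np.concatenate([[0.0], fpr, [1.0]])
        tpr = np.concatenate([[0.0], tpr, [1.0]])
        return cls(fpr, tpr)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


@dataclass
class AUCResult:
    """Per-replicate out-of-sample AUCs with median and percentile CI."""

    name: str
    aucs: np.ndarray
    n_failed: int = 0

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.aucs, 2.5)),
            float(np.percentile(self.aucs, 97.5)),
        )


def _score_split(model: ModelSpec, train: Cohort, test: Cohort) -> np.ndarray | None:
    """Test-half linear predictor; None when a refit fails to converge."""
    Xt = test.design_matrix(model.variables)
    if model.refit:
        f = fit_logistic(train.design_matrix(model.variables), train.status.astype(float), model.variables)
        if not f.converged:
            return None
        return Xt @ f.coef
    beta = np.concatenate([[model.intercept or 0.0], model.coefficient_vector()])
    return Xt @ beta


def crossval_evaluate(
    cohort: Cohort,
    model: ModelSpec,
    n_replicates: int,
    master_seed: int,
    donor_mode: str = "all",
    stratified: bool = False,
) -> AUCResult:
    """Out-of-sample AUC of one model over the replicate schedule.

    Per replicate: impute, split, refit the model's variable set on the
    training half (or apply its fixed coefficients), score the test half
    by linear predictor and take the rank AUC.  Replicates whose refit
    does not converge are dropped and counted in ``n_failed``.
    """
    table, _, _ = compare_models(
        cohort, [model], n_replicates, master_seed,
        donor_mode=donor_mode, stratified=stratified, collect_roc=False,
    )
    return table[0]


def compare_models(
    cohort: Cohort,
    models: Sequence[ModelSpec],
    n_replicates: int,
    master_seed: int,
    donor_mode: str = "all",
    stratified: bool = False,
    collect_roc: bool = True,
    roc_grid: int = 101,
) -> tuple[list[AUCResult], dict[str, ROCCurve], dict[str, ROCCurve]]:
    """Evaluate several models on the SAME imputations and splits.

    Returns one :class:`AUCResult` per model plus two ROC renderings per
    model: "pooled" (all test-half scores pooled over replicates, one
    curve) and "averaged" (per-replicate curves averaged on a common
    false-positive-rate grid).
    """
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise CohortError("model names must be unique for comparison")
    for m in models:
        missing = [v for v in m.variables if v not in cohort.var_names]
        if missing:
            raise CohortError(f"model {m.name!r}: variable(s) {missing} absent from cohort")
    aucs: dict[str, list[float]] = {n: [] for n in names}
    failed = {n: 0 for n in names}
    pooled_scores: dict[str, list[np.ndarray]] = {n: [] for n in names}
    pooled_status: dict[str, list[np.ndarray]] = {n: [] for n in names}
    grid = np.linspace(0.0, 1.0, roc_grid)
    mean_tpr: dict[str, np.ndarray] = {n: np.zeros(roc_grid) for n in names}
    mean_tpr_n = {n: 0 for n in names}

    for i in range(n_replicates):
        rng = np.random.default_rng(replicate_seed(master_seed, i))
        complete, plan = replicate_data(cohort, rng, i, donor_mode, stratified)
        train = complete.subset(plan.train_ids)
        test = complete.subset(plan.test_ids)
        case = test.case_mask
        for m in models:
            eta = _score_split(m, train, test)
            if eta is None:
                failed[m.name] += 1
                continue
            aucs[m.name].append(auc_rank(eta[case], eta[~case]))
            if collect_roc:
                pooled_scores[m.name].append(eta)
                pooled_status[m.name].append(test.status)
                fpr, tpr, _ = roc_curve(test.status, eta)
                mean_tpr[m.name] += np.interp(grid, fpr, tpr)
                mean_tpr_n[m.name] += 1

    results = []
    for n in names:
        if not aucs[n]:
            raise CohortError(f"model {n!r}: every replicate refit failed")
        results.append(AUCResult(n, np.asarray(aucs[n]), failed[n]))
    pooled: dict[str, ROCCurve] = {}
    averaged: dict[str, ROCCurve] = {}
    if collect_roc:
        for n in names:
            pooled[n] = ROCCurve.from_scores(
                np.concatenate(pooled_scores[n]), np.concatenate(pooled_status[n])
            )
            tpr = mean_tpr[n] / max(mean_tpr_n[n], 1)
            tpr[0], tpr[-1] = 0.0, 1.0
            averaged[n] = ROCCurve(grid, np.maximum.accumulate(tpr))
    return results, pooled, averaged


def comparison_table(results: Sequence[AUCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.name,
                "median_auc": r.median_auc,
                "ci_lo": r.ci95[0],
                "ci_hi": r.ci95[1],
                "n_replicates": r.aucs.size,
                "n_failed": r.n_failed,
            }
            for r in results
        ]
    )


def score_individuals(model: ModelSpec, records: pd.DataFrame, missing: str = "error") -> pd.DataFrame:
    """Linear predictor (and probability, when an intercept exists) per row.

    ``missing="error"`` (default) rejects rows with a missing model
    covariate; ``missing="zero"`` scores them with the missing covariate
    contributing nothing.
    """
    if hasattr(model, "to_model_spec"):  # EnsembleModel
        model = model.to_model_spec(refit=False)
    if model.refit or any(model.coefficients.get(v) is None for v in model.variables):
        raise CohortError(f"model {model.name!r} has no fixed coefficients to score with")
    unknown = [v for v in model.variables if v not in records.columns]
    if unknown:
        raise CohortError(f"records lack model variable(s): {unknown}")
    X = records[model.variables].to_numpy(dtype=float)
    nan = np.isnan(X)
    if nan.any():
        if missing == "error":
            bad = records.index[nan.any(axis=1)].tolist()
            raise CohortError(f"missing covariate values in rows {bad}; pass missing='zero' to score anyway")
        elif missing == "zero":
            X = np.where(nan, 0.0, X)
        else:
            raise CohortError(f"unknown missing policy {missing!r}")
    beta = model.coefficient_vector()
    score = X @ beta
    out = pd.DataFrame({"score": score}, index=records.index)
    if model.intercept is not None:
        lp = model.intercept + score
        out["score"] = lp
        out["probability"] = 1.0 / (1.0 + np.exp(-lp))
    return out


def plot_roc(curves: dict[str, ROCCurve], path: str, title: str = "ROC") -> None:
    """Write a ROC figure (one line per model) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, c in curves.items():
        ax.plot(c.fpr, c.tpr, label=f"{name} (AUC {c.area:.2f})")
    ax.plot([0, 1], [0, 1], color="lightgrey", lw=1)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
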