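"""Per-replicate stepwise-AIC logistic selection and ensemble aggregation.

The base learner is a logistic regression fitted by Newton/IRLS.  Each
replicate hot-deck-imputes the cohort, splits it in half, and runs a
greedy bidirectional stepwise search from the intercept-only model,
accepting the single-variable addition or deletion with the lowest AIC as
long as it strictly improves the current AIC.  Across replicates the
per-variable coefficients are aggregated by their median with unselected
runs counted as zero — a shrinkage that protects the reported effect
sizes from winner's curse — and the median standard error is taken over
the runs in which the variable was selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, CohortError
from .resample import hot_deck_impute, random_split, replicate_seed

MAX_ABS_BETA = 30.0  # |log-OR| beyond this is treated as separation


@dataclass
class FitResult:
    """One logistic maximum-likelihood fit.

    ``coef[0]`` is the intercept; ``coef[1:]`` align with ``variables``.
    ``se`` is None when the fit did not converge (separation, singular
    information, or iteration cap) — exploded coefficients are never
    reported silently.
    """

    variables: list[str]
    coef: np.ndarray
    se: np.ndarray | None
    loglik: float
    aic: float
    converged: bool
    n_iter: int


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    variables: Sequence[str] = (),
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Logistic MLE by Newton iteration with step halving.

    ``X`` must already contain the intercept column.  Convergence when the
    log-likelihood improves by less than ``tol``; standard errors come
    from the inverse observed information at the optimum.  AIC is
    ``2k - 2 loglik`` with k the number of estimated parameters.
    """
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if not (0 < y.sum() < n):
        raise CohortError("need at least one case and one control to fit")
    beta = np.zeros(k) if start is None else np.asarray(start, dtype=float).copy()
    eta = X @ beta
    ll = _loglik(eta, y)
    converged = False
    singular = False
    it = 0
    for it in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            singular = True
            break
        # step halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            eta_new = X @ beta_new
            ll_new = _loglik(eta_new, y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, eta = beta_new, eta_new
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    if np.abs(beta).max() > MAX_ABS_BETA:
        converged = False  # quasi-complete separation: likelihood flat in a diverging direction
    se: np.ndarray | None = None
    if converged and not singular:
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if (d <= 0).any() or not np.isfinite(d).all():
                converged, se = False, None
            else:
                se = np.sqrt(d)
        except np.linalg.LinAlgError:
            converged, se = False, None
    else:
        converged = False
    aic = 2.0 * k - 2.0 * ll
    return FitResult(list(variables), beta, se, ll, aic, converged, it)


def fit_logistic_cohort(cohort: Cohort, variables: Sequence[str]) -> FitResult:
    """Convenience wrapper: fit on a complete cohort's named columns."""
    X = cohort.design_matrix(variables)
    return fit_logistic(X, cohort.status.astype(float), variables)


@dataclass
class ReplicateResult:
    """One replicate's selected model (and, once evaluated, its test AUC)."""

    replicate_index: int
    seed: int
    selected: list[str]
    fit: FitResult
    aic_path: list[float]
    n_skipped_moves: int = 0
    test_auc: float | None = None


def stepwise_select(
    train: Cohort,
    candidates: Sequence[str],
    direction: str = "both",
    forced: Sequence[str] = (),
    max_steps: int = 200,
) -> ReplicateResult:
    """Greedy stepwise-AIC search over candidate variables.

    Starts from the intercept-only model (plus any ``forced`` variables,
    which are never deleted); at each iteration evaluates every
    single-variable addition and — for direction "both"/"backward" —
    every deletion, and applies the move with the lowest AIC if that AIC
    is strictly below the current one.  Moves whose fit does not converge
    (e.g. a rare allele separating a half-cohort) are skipped.  Ties are
    broken by evaluation order: additions before deletions, each in
    lexicographic variable-name order.
    """
    if direction not in ("both", "forward", "backward"):
        raise CohortError(f"unknown stepwise direction {direction!r}")
    unknown = [v for v in list(candidates) + list(forced) if v not in train.var_names]
    if unknown:
        raise CohortError(f"unknown candidate variable(s): {unknown}")
    y = train.status.astype(float)
    cols = {v: train.column(v) for v in set(candidates) | set(forced)}
    if any(np.isnan(c).any() for c in cols.values()):
        raise CohortError("stepwise_select requires a complete (imputed) training cohort")
    ones = np.ones(train.n_samples)
    forced = sorted(set(forced))

    def _fit(sel: list[str], start=None) -> FitResult:
        X = np.column_stack([ones] + [cols[v] for v in sel]) if sel else ones[:, None]
        return fit_logistic(X, y, sel, start=start)

    if direction == "backward":
        selected = sorted(set(candidates) | set(forced))
    else:
        selected = list(forced)
    cur = _fit(selected)
    if not cur.converged:
        # fall back to the empty (or forced-only, cold-start) model
        raise CohortError(f"initial stepwise model on {selected} did not converge")
    aic_path = [cur.aic]
    n_skipped = 0
    in_model = set(selected)

    for _ in range(max_steps):
        best_fit: FitResult | None = None
        best_sel: list[str] | None = None
        if direction in ("both", "forward"):
            for v in sorted(set(candidates) - in_model):
                trial = selected + [v]
                f = _fit(trial, start=np.append(cur.coef, 0.0))
                if not f.converged:
                    n_skipped += 1
                    continue
                if f.aic < cur.aic - 1e-10 and (best_fit is None or f.aic < best_fit.aic - 1e-10):
                    best_fit, best_sel = f, trial
        if direction in ("both", "backward"):
            for v in sorted(in_model - set(forced)):
                i = selected.index(v)
                trial = selected[:i] + selected[i + 1 :]
                f = _fit(trial, start=np.delete(cur.coef, i + 1))
                if not f.converged:
                    n_skipped += 1
                    continue
                if f.aic < cur.aic - 1e-10 and (best_fit is None or f.aic < best_fit.aic - 1e-10):
                    best_fit, best_sel = f, trial
        if best_fit is None:
            break
        cur, selected = best_fit, best_sel
        in_model = set(selected)
        aic_path.append(cur.aic)

    return ReplicateResult(0, 0, selected, cur, aic_path, n_skipped)


def replicate_data(cohort: Cohort, rng, replicate_index: int, donor_mode: str = "all", stratified: bool = False):
    """One replicate's (complete cohort, split plan) under the seed schedule.

    donor_mode "all": impute from all non-missing control values, then
    split (the default protocol; carries a minor train/test leak through
    the shared donor pool).  donor_mode "train": split first, then impute
    with donors restricted to training-set controls (strict mode).
    """
    if donor_mode == "all":
        complete = hot_deck_impute(cohort, rng)
        plan = random_split(complete, rng, replicate_index, stratified)
    elif donor_mode == "train":
        plan = random_split(cohort, rng, replicate_index, stratified)
        complete = hot_deck_impute(cohort, rng, donor_ids=plan.train_ids)
    else:
        raise CohortError(f"unknown donor_mode {donor_mode!r}")
    return complete, plan


def run_ensemble(
    cohort: Cohort,
    candidates: Sequence[str],
    n_replicates: int,
    master_seed: int,
    direction: str = "both",
    forced: Sequence[str] = (),
    donor_mode: str = "all",
    stratified: bool = False,
    compute_test_auc: bool = True,
) -> list[ReplicateResult]:
    """Run the split/impute/stepwise pipeline for ``n_replicates`` replicates.

    Fully deterministic given ``master_seed``; replicate i uses its own
    generator seeded with ``(master_seed XOR i) & 0x7FFFFFFF`` so results
    do not depend on execution order.
    """
    from .evaluate import auc_rank  # local import to avoid a module cycle

    if n_replicates < 1:
        raise CohortError("n_replicates must be >= 1")
    out: list[ReplicateResult] = []
    for i in range(n_replicates):
        rs = replicate_seed(master_seed, i)
        rng = np.random.default_rng(rs)
        try:
            complete, plan = replicate_data(cohort, rng, i, donor_mode, stratified)
            train = complete.subset(plan.train_ids)
            rr = stepwise_select(train, candidates, direction=direction, forced=forced)
        except CohortError as exc:
            raise CohortError(f"replicate {i}: {exc}") from exc
        rr.replicate_index = i
        rr.seed = rs
        if compute_test_auc:
            test = complete.subset(plan.test_ids)
            eta = test.design_matrix(rr.selected) @ rr.fit.coef
            rr.test_auc = auc_rank(eta[test.case_mask], eta[~test.case_mask])
        out.append(rr)
    return out


# ---------------------------------------------------------------------------
# Aggregation


@dataclass
class VariableSummary:
    name: str
    median_coefficient: float
    median_se: float | None
    selection_frequency: float
    odds_ratio: float
    ci95: tuple[float, float] | None
    p: float | None
    q: float | None = None


@dataclass
class EnsembleModel:
    """Median-aggregated ensemble over stepwise replicates.

    Per variable: the median coefficient over ALL replicates with
    unselected runs counted as zero; the median SE over the replicates in
    which the variable was selected; OR = exp(median coefficient) with a
    1.96-SE Wald 95% CI; two-sided Wald p; Benjamini-Hochberg q.  The
    intercept is the median intercept over all replicates so the final
    model can emit calibrated probabilities.
    """

    name: str
    variables: list[VariableSummary]
    intercept: float
    n_replicates: int
    mean_n_selected: float

    @property
    def selected_variables(self) -> list[str]:
        return [v.name for v in self.variables if v.median_coefficient != 0.0]

    def summary(self, name: str) -> VariableSummary:
        for v in self.variables:
            if v.name == name:
                return v
        raise CohortError(f"unknown variable {name!r}")

    def to_model_spec(self, nonzero_only: bool = True, refit: bool = False):
        from .cohort import ModelSpec

        keep = [v for v in self.variables if (v.median_coefficient != 0.0 or not nonzero_only)]
        return ModelSpec(
            name=self.name,
            variables=[v.name for v in keep],
            coefficients={v.name: v.median_coefficient for v in keep},
            se={v.name: v.median_se for v in keep},
            selection_frequency={v.name: v.selection_frequency for v in keep},
            intercept=self.intercept,
            refit=refit,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for v in self.variables:
            rows.append(
                {
                    "variable": v.name,
                    "median_coefficient": v.median_coefficient,
                    "median_se": np.nan if v.median_se is None else v.median_se,
                    "selection_frequency": v.selection_frequency,
                    "odds_ratio": v.odds_ratio,
                    "ci95_lo": np.nan if v.ci95 is None else v.ci95[0],
                    "ci95_hi": np.nan if v.ci95 is None else v.ci95[1],
                    "p": np.nan if v.p is None else v.p,
                    "q": np.nan if v.q is None else v.q,
                }
            )
        return pd.DataFrame(rows)


def aggregate_ensemble(
    replicates: Sequence[ReplicateResult],
    candidates: Sequence[str],
    name: str = "ensemble",
    fdr_level: float = 0.05,
) -> EnsembleModel:
    """Aggregate replicate fits into the final median-coefficient model."""
    if not replicates:
        raise CohortError("need at least one replicate to aggregate")
    cand = list(candidates)
    idx = {v: j for j, v in enumerate(cand)}
    R = len(replicates)
    coefs = np.zeros((R, len(cand)))
    sel = np.zeros((R, len(cand)), dtype=bool)
    ses: list[list[float]] = [[] for _ in cand]
    intercepts = np.empty(R)
    for r, rr in enumerate(replicates):
        intercepts[r] = rr.fit.coef[0]
        for pos, v in enumerate(rr.fit.variables):
            j = idx.get(v)
            if j is None:
                continue
            coefs[r, j] = rr.fit.coef[pos + 1]
            sel[r, j] = True
            if rr.fit.se is not None:
                ses[j].append(float(rr.fit.se[pos + 1]))

    med_coef = np.median(coefs, axis=0)
    sel_freq = sel.mean(axis=0)
    summaries: list[VariableSummary] = []
    pvals: list[float] = []
    p_index: list[int] = []
    for j, v in enumerate(cand):
        if ses[j]:
            med_se = float(np.median(ses[j]))
            z = med_coef[j] / med_se
            p = float(2.0 * stats.norm.sf(abs(z)))
            with np.errstate(over="ignore"):  # huge SEs on tiny data -> inf bound
                ci = (
                    float(np.exp(med_coef[j] - 1.96 * med_se)),
                    float(np.exp(med_coef[j] + 1.96 * med_se)),
                )
            p_index.append(j)
            pvals.append(p)
        else:
            med_se, p, ci = None, None, None
        summaries.append(
            VariableSummary(
                v, float(med_coef[j]), med_se, float(sel_freq[j]),
                float(np.exp(med_coef[j])), ci, p,
            )
        )
    if pvals:
        q = multipletests(pvals, alpha=fdr_level, method="fdr_bh")[1]
        for j, qv in zip(p_index, q):
            summaries[j].q = float(qv)
    mean_n_selected = float(np.mean([len(rr.selected) for rr in replicates]))
    return EnsembleModel(name, summaries, float(np.median(intercepts)), R, mean_n_selected)


def ensemble_report(model: EnsembleModel, cohort: Cohort) -> pd.DataFrame:
    """Report table in the style of the study's model table: per selected
    variable, the gene/effect-allele annotation, case and control allele
    frequency (genotype) or mean/percent (clinical), OR, CI, p, q and
    selection frequency."""
    from .qc import allele_frequency

    rows = []
    for v in model.variables:
        if v.median_coefficient == 0.0:
            continue
        meta = cohort.meta(v.name)
        if meta.kind == "genotype":
            case_stat, _ = allele_frequency(cohort, v.name, "cases")
            ctrl_stat, _ = allele_frequency(cohort, v.name, "controls")
        else:
            col = cohort.column(v.name)
            cm, km = cohort.case_mask, ~cohort.case_mask
            case_stat = float(np.nanmean(col[cm]))
            ctrl_stat = float(np.nanmean(col[km]))
            if meta.kind == "binary":
                case_stat *= 100.0
                ctrl_stat *= 100.0
        rows.append(
            {
                "variable": v.name,
                "gene": meta.gene_label or "",
                "effect_allele": meta.effect_allele or "",
                "case_stat": case_stat,
                "control_stat": ctrl_stat,
                "odds_ratio": v.odds_ratio,
                "ci95_lo": np.nan if v.ci95 is None else v.ci95[0],
                "ci95_hi": np.nan if v.ci95 is None else v.ci95[1],
                "p": np.nan if v.p is None else v.p,
                "q": np.nan if v.q is None else v.q,
                "selection_frequency": v.selection_frequency,
            }
        )
    return pd.DataFrame(rows)


def replicate_log(replicates: Sequence[ReplicateResult]) -> list[dict]:
    """JSON-serializable audit log of selected sets, AIC paths and seeds."""
    return [
        {
            "replicate_index": rr.replicate_index,
            "seed": rr.seed,
            "selected": list(rr.selected),
            "aic_path": [float(a) for a in rr.aic_path],
            "n_skipped_moves": rr.n_skipped_moves,
            "test_auc": rr.test_auc,
        }
        for rr in replicates
    ]


def interaction_screen(cohort: Cohort, variables: Sequence[str]) -> pd.DataFrame:
    """Post-hoc pairwise interaction Wald screen among selected variables.

    For each pair, refits the main-effects model plus the single product
    term on the complete cohort and reports the interaction Wald p.  This
    is a diagnostic only — interactions are never part of selection.
    """
    rows = []
    base = list(variables)
    for a_i in range(len(base)):
        for b_i in range(a_i + 1, len(base)):
            a, b = base[a_i], base[b_i]
            X = cohort.design_matrix(base)
            prod = (cohort.column(a) * cohort.column(b))[:, None]
            f = fit_logistic(np.hstack([X, prod]), cohort.status.astype(float), base + [f"{a}:{b}"])
            if f.converged and f.se is not None:
                z = f.coef[-1] / f.se[-1]
                p = float(2.0 * stats.norm.sf(abs(z)))
            else:
                p = np.nan
            rows.append({"a": a, "b": b, "coefficient": f.coef[-1], "p": p, "converged": f.converged})
    return pd.DataFrame(rows)
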