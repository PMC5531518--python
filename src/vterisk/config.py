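"""Run configuration and end-to-end orchestration.

``run_pipeline`` ties the stages together: read (or receive) a cohort,
apply the allele-frequency QC filter, run the split/impute/stepwise
ensemble over the surviving candidates, aggregate to the final model, and
evaluate it against the registry comparison models on the shared replicate
schedule.  Every output is written atomically and the run is fully
deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import evaluate, qc
from .cohort import (
    Cohort,
    CohortError,
    ModelSpec,
    VariableMeta,
    read_cohort_csv,
    read_model_json,
    validate_cohort,
    write_model_json,
)
from .ensemble import aggregate_ensemble, ensemble_report, replicate_log, run_ensemble

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    cohort_path: str
    schema_path: str
    output_dir: str
    reference_af_path: str | None = None
    model_spec_paths: list[str] = field(default_factory=list)
    registry_models: list[str] = field(default_factory=lambda: ["clinical4", "genetic9", "combined13"])
    n_replicates: int = 10_000
    master_seed: int = 1
    direction: str = "both"
    donor_mode: str = "all"
    stratified: bool = False
    qc_alpha: float = 0.01
    fdr_level: float = 0.05
    force_include: list[str] = field(default_factory=list)
    candidates: list[str] | None = None  # None: every schema variable
    make_plots: bool = True

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise CohortError("n_replicates must be >= 1")
        if not 0.0 < self.qc_alpha < 1.0:
            raise CohortError("qc_alpha must be in (0,1)")
        if not 0.0 < self.fdr_level < 1.0:
            raise CohortError("fdr_level must be in (0,1)")
        if self.direction not in ("both", "forward", "backward"):
            raise CohortError(f"unknown stepwise direction {self.direction!r}")
        if self.donor_mode not in ("all", "train"):
            raise CohortError(f"unknown donor_mode {self.donor_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CohortError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def read_schema_yaml(path: str | os.PathLike) -> list[VariableMeta]:
    """Schema file: a YAML list of {name, kind, effect_allele?, gene_label?}."""
    with open(path, encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    return [
        VariableMeta(
            e["name"], e["kind"], e.get("effect_allele"), e.get("gene_label")
        )
        for e in entries
    ]


def write_schema_yaml(schema: list[VariableMeta], path: str | os.PathLike) -> None:
    entries = [
        {k: v for k, v in dataclasses.asdict(m).items() if v is not None} for m in schema
    ]
    _atomic_write(path, yaml.safe_dump(entries, sort_keys=False))


def _atomic_write(path, text: str) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
    os.replace(tmp, path)


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> Path:
    """Execute QC -> ensemble -> aggregation -> model comparison.

    Returns the output directory.  Any stage failure aborts with the stage
    name in the exception message.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    # -- stage: load ------------------------------------------------------
    try:
        if cohort is None:
            schema = read_schema_yaml(config.schema_path)
            cohort = read_cohort_csv(config.cohort_path, schema)
        problems = validate_cohort(cohort)
        if problems:
            raise CohortError("; ".join(problems))
    except CohortError as exc:
        raise CohortError(f"[load] {exc}") from exc

    # -- stage: QC --------------------------------------------------------
    discarded: list[str] = []
    try:
        if config.reference_af_path:
            reference = qc.read_reference_af(config.reference_af_path)
            comparisons = qc.fisher_af_filter(cohort, reference, alpha=config.qc_alpha)
            qc_df = qc.qc_report(comparisons)
            _atomic_write(out / "qc_report.csv", qc_df.to_csv(index=False))
            discarded = [c.variant for c in comparisons if not c.keep]
            if discarded:
                log.info("QC discarded variant(s): %s", discarded)
        desc = qc.descriptive_dataframe(qc.descriptive_table(cohort))
        _atomic_write(out / "descriptives.csv", desc.to_csv(index=False))
    except CohortError as exc:
        raise CohortError(f"[qc] {exc}") from exc

    candidates = config.candidates if config.candidates is not None else cohort.var_names
    candidates = [v for v in candidates if v not in discarded]

    # -- stage: models ----------------------------------------------------
    models: list[ModelSpec] = []
    try:
        for name in config.registry_models:
            models.append(evaluate.registry_model(name))
        for p in config.model_spec_paths:
            models.append(read_model_json(p))
        for m in models:
            bad = [v for v in m.variables if v in discarded]
            if bad:
                raise CohortError(f"model {m.name!r} uses QC-discarded variant(s) {bad}")
    except CohortError as exc:
        raise CohortError(f"[models] {exc}") from exc

    # -- stage: ensemble --------------------------------------------------
    try:
        replicates = run_ensemble(
            cohort, candidates, config.n_replicates, config.master_seed,
            direction=config.direction, forced=config.force_include,
            donor_mode=config.donor_mode, stratified=config.stratified,
        )
        model = aggregate_ensemble(replicates, candidates, name="ensemble", fdr_level=config.fdr_level)
        write_model_json(model, out / "ensemble_model.json")
        _atomic_write(out / "ensemble_table.csv", ensemble_report(model, cohort).to_csv(index=False))
        _atomic_write(
            out / "replicate_log.jsonl",
            "".join(json.dumps(r) + "\n" for r in replicate_log(replicates)),
        )
        n_unconverged = sum(1 for r in replicates if not r.fit.converged)
        log.info(
            "ensemble: %d replicates, mean %.1f variables selected, %d final, %d unconverged final fits",
            len(replicates), model.mean_n_selected, len(model.selected_variables), n_unconverged,
        )
    except CohortError as exc:
        raise CohortError(f"[ensemble] {exc}") from exc

    # -- stage: evaluation ------------------------------------------------
    try:
        final_spec = model.to_model_spec(refit=True)
        final_spec.name = "ensemble_selected"
        all_models = [m for m in models] + [final_spec]
        results, pooled, averaged = evaluate.compare_models(
            cohort, all_models, config.n_replicates, config.master_seed,
            donor_mode=config.donor_mode, stratified=config.stratified,
        )
        _atomic_write(out / "auc_comparison.csv", evaluate.comparison_table(results).to_csv(index=False))
        for name, curve in pooled.items():
            _atomic_write(out / f"roc_pooled_{name}.csv", curve.to_dataframe().to_csv(index=False))
        for name, curve in averaged.items():
            _atomic_write(out / f"roc_averaged_{name}.csv", curve.to_dataframe().to_csv(index=False))
        if config.make_plots:
            evaluate.plot_roc(pooled, str(out / "roc_pooled.png"), "Pooled test-set ROC")
            evaluate.plot_roc(averaged, str(out / "roc_averaged.png"), "Split-averaged ROC")
    except CohortError as exc:
        raise CohortError(f"[evaluate] {exc}") from exc

    return out
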