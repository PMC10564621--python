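"""The model ladder: single-measure baselines vs the selected scan model.

For each outcome (RFM, VAT, SMI) and each sex stratum a ladder of nested
regression models is fitted and bootstrap-validated:

* ``age`` and ``lifestyle`` alone,
* each single anthropometric baseline (BMI, WC, WHtR; for SMI additionally
  forearm and thigh girths), then the same + age, then + age + lifestyle,
* the stability-selected scan-variable model, + age, + age + lifestyle.

"Lifestyle" counts as 3 variables (education, activity, diet) regardless of
dummy expansion, so e.g. "BMI + age + lifestyle" has N = 5.  Each row
reports the apparent adjusted R^2 of the full-data fit alongside the mean
out-of-bag R^2 and RMSE from bootstrap validation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .cohort import CohortTable
from .errors import UsageError
from .evaluate import bootstrap_validate
from .selection import (
    DesignSpec,
    SelectionResult,
    StabilitySelection,
    design_matrix,
    fit_ols,
)

log = logging.getLogger(__name__)

#: single-measure baselines per outcome; forearm/thigh girths are muscle
#: proxies and apply to SMI only.
STANDARD_BASELINES = {
    "rfm": ("bmi", "wc", "whtr"),
    "vat": ("bmi", "wc", "whtr"),
    "smi": ("bmi", "wc", "whtr", "forearm_girth", "thigh_girth"),
}


@dataclass
class ModelLadderSpec:
    """One ladder cell family: outcome and sex, plus which models to fit."""

    outcome: str
    sex: str
    baselines: tuple[str, ...] | None = None  # default: STANDARD_BASELINES[outcome]
    include_null_models: bool = True  # age-only and lifestyle-only rows
    include_scan: bool = True
    augmentations: tuple[tuple[str, ...], ...] = ((), ("age",), ("age", "lifestyle"))

    def resolved_baselines(self) -> tuple[str, ...]:
        if self.baselines is not None:
            return tuple(self.baselines)
        if self.outcome not in STANDARD_BASELINES:
            raise UsageError(f"unknown outcome {self.outcome!r}")
        return STANDARD_BASELINES[self.outcome]


def _model_rows(spec: ModelLadderSpec, selection: SelectionResult | None):
    """Yield (label, candidate variables, n_variables, family) per ladder model."""
    if spec.include_null_models:
        yield "age", (), ("age",), 1, "null"
        yield "lifestyle", (), ("lifestyle",), 3, "null"
    for base in spec.resolved_baselines():
        for aug in spec.augmentations:
            label = " + ".join([base, *aug])
            n_vars = 1 + sum(3 if a == "lifestyle" else 1 for a in aug)
            yield label, (base,), aug, n_vars, "standard"
    if spec.include_scan:
        if selection is None:
            raise UsageError("scan-variable models require a SelectionResult")
        stable = tuple(selection.stable_set)
        for aug in spec.augmentations:
            label = " + ".join(["scan variables", *aug])
            n_vars = len(stable) + sum(3 if a == "lifestyle" else 1 for a in aug)
            yield label, stable, aug, n_vars, "scan"


def run_ladder(
    cohort: CohortTable,
    outcome: str,
    sex: str,
    selection: SelectionResult | None = None,
    spec: ModelLadderSpec | None = None,
    validate_iterations: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit and validate every model of the ladder for one outcome and sex.

    Returns one row per model with columns (outcome, sex, model, family,
    n_variables, r2, adj_r2, oob_r2, rmse).  ``r2``/``adj_r2`` are the
    apparent full-data values; ``oob_r2``/``rmse`` are means over the
    bootstrap out-of-bag iterations.
    """
    if spec is None:
        spec = ModelLadderSpec(outcome=outcome, sex=sex)
    stratum = cohort.stratum(sex)
    rows = []
    for i, (label, candidates, aug, n_vars, family) in enumerate(_model_rows(spec, selection)):
        if not candidates and not aug:
            log.warning("skipping ladder model %r: no predictors (empty stable set?)", label)
            continue
        dspec = DesignSpec(
            outcome=outcome,
            candidates=tuple(candidates),
            include_age="age" in aug,
            include_lifestyle="lifestyle" in aug,
        )
        X, y, _ = design_matrix(stratum, dspec)
        if X.shape[1] == 0:
            raise UsageError(f"ladder model {label!r} has no predictors")
        fit = fit_ols(X, y)
        val = bootstrap_validate(
            X, y, iterations=validate_iterations, seed=None if seed is None else seed + i
        )
        rows.append(
            {
                "outcome": outcome,
                "sex": sex,
                "model": label,
                "family": family,
                "n_variables": n_vars,
                "r2": fit.rsquared,
                "adj_r2": fit.rsquared_adj,
                "oob_r2": val.mean_oob_r2,
                "rmse": val.mean_oob_rmse,
            }
        )
    return pd.DataFrame(rows)


def improvement_summary(table: pd.DataFrame, metric: str = "adj_r2") -> pd.DataFrame:
    """Per (outcome, sex): best scan-model minus best standard-measure model.

    The delta is in percentage points of explained variation; sign free.
    Raises if either model family is missing for a requested outcome/sex.
    """
    out = []
    for (outcome, sex), grp in table.groupby(["outcome", "sex"]):
        scan = grp[grp["family"] == "scan"]
        std = grp[grp["family"] == "standard"]
        if scan.empty or std.empty:
            raise UsageError(
                f"both scan and standard families required for {outcome}/{sex}"
            )
        best_scan = scan[metric].max()
        best_std = std[metric].max()
        out.append(
            {
                "outcome": outcome,
                "sex": sex,
                "best_scan": best_scan,
                "best_standard": best_std,
                "delta_points": 100.0 * (best_scan - best_std),
            }
        )
    return pd.DataFrame(out)


@dataclass
class PipelineResult:
    comparison: pd.DataFrame
    selections: dict[tuple[str, str], SelectionResult] = field(default_factory=dict)


def run_pipeline(
    cohort: CohortTable,
    outcomes: Sequence[str] = ("rfm", "vat", "smi"),
    sexes: Sequence[str] = ("male", "female"),
    n_boot: int = 2000,
    threshold: float = 0.70,
    validate_iterations: int | None = None,
    seed: int | None = None,
    candidates: Sequence[str] | None = None,
) -> PipelineResult:
    """Stability selection + ladder for every outcome and sex stratum.

    Selection is rerun independently per (outcome, sex); selected sets are
    never shared across strata.  All randomness derives from ``seed``.
    """
    if validate_iterations is None:
        validate_iterations = n_boot
    comparison = []
    selections: dict[tuple[str, str], SelectionResult] = {}
    stage = 0
    for sex in sexes:
        for outcome in outcomes:
            stage += 1
            log.info("stability selection: outcome=%s sex=%s", outcome, sex)
            model = StabilitySelection.from_cohort(
                cohort, outcome=outcome, sex=sex, candidates=candidates
            )
            res = model.fit(
                n_boot=n_boot,
                threshold=threshold,
                seed=None if seed is None else seed + 1000 * stage,
            )
            selections[(outcome, sex)] = res.selection
            log.info("stable set (%s, %s): %s", outcome, sex, res.selection.stable)
            table = run_ladder(
                cohort,
                outcome,
                sex,
                selection=res.selection,
                validate_iterations=validate_iterations,
                seed=None if seed is None else seed + 1000 * stage + 500,
            )
            comparison.append(table)
    return PipelineResult(comparison=pd.concat(comparison, ignore_index=True), selections=selections)
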