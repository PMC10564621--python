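"""Bootstrap-stabilised backward-elimination variable selection.

The selection procedure works in two stages.  First, AIC-based backward
elimination is rerun on ``B`` bootstrap resamples of the data; the fraction
of resamples in which a candidate survives is its *inclusion frequency*, and
the coefficients it receives in those resamples form its bootstrap draw
distribution.  Second, candidates whose inclusion frequency exceeds a
threshold (70% by default) are kept only if the 95% bias-corrected and
accelerated (BCa) interval of their coefficient draws does not straddle
zero -- i.e. the variable has an unambiguously positive or negative effect.

Categorical covariates enter and leave elimination as whole dummy blocks.

The module exposes both the individual operations (:func:`backward_eliminate`,
:func:`bootstrap_selection`, :func:`bca_interval`, :func:`stable_set`) and a
statsmodels-style model class :class:`StabilitySelection` whose ``fit``
returns a :class:`StabilitySelectionResults`.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import ndtr, ndtri

from .cohort import LIFESTYLE_GROUPS, CohortTable, add_lifestyle_dummies
from .errors import SingularDesignError, UsageError

log = logging.getLogger(__name__)

OUTCOME_DESIGN_COLUMNS = {"rfm": "rfm_pct", "vat": "vat_kg", "smi": "smi"}
_ALIASES = {
    "wc": "waist_girth",
    "thigh_girth": "thigh_girth_horizontal",
    "height": "height_cm",
}


# ---------------------------------------------------------------------------
# OLS and the Gram-matrix stepwise engine
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """One ordinary-least-squares fit (via statsmodels)."""

    params: pd.Series
    resid: np.ndarray
    fittedvalues: np.ndarray
    rsquared: float
    rsquared_adj: float
    aic: float
    nobs: int
    exog_names: list[str]


def _collinear_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of columns beyond the numerical rank, by pivoted QR."""
    _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [names[j] for j in sorted(piv[rank:])]


def fit_ols(exog: pd.DataFrame, endog: Sequence[float]) -> ModelFit:
    """Least-squares fit with intercept; R^2, adjusted R^2 and AIC.

    Raises :class:`SingularDesignError` naming the collinear (or constant)
    columns when the design is rank deficient.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(exog).astype(float)
    y = np.asarray(endog, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise UsageError(f"need n > p+1 observations (n={n}, p={p})")
    const = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if const:
        raise SingularDesignError(const, f"constant columns besides intercept: {const}")
    design = sm.add_constant(X, has_constant="raise")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        bad = _collinear_columns(design.to_numpy(), list(design.columns))
        raise SingularDesignError(bad)
    res = sm.OLS(y, design).fit()
    return ModelFit(
        params=res.params,
        resid=np.asarray(res.resid),
        fittedvalues=np.asarray(res.fittedvalues),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        aic=float(res.aic),
        nobs=int(res.nobs),
        exog_names=list(X.columns),
    )


class _Gram:
    """Centered sufficient statistics; subset RSS in O(k^3) independent of n."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.n = len(y)
        self.Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        self.G = self.Xc.T @ self.Xc
        self.c = self.Xc.T @ yc
        self.yy = float(yc @ yc)

    def solve(self, cols: Sequence[int]) -> np.ndarray | None:
        """Slope coefficients for the column subset, or None if singular."""
        if len(cols) == 0:
            return np.empty(0)
        ix = np.ix_(cols, cols)
        try:
            cf = scipy.linalg.cho_factor(self.G[ix], check_finite=False)
        except (scipy.linalg.LinAlgError, ValueError):
            return None
        return scipy.linalg.cho_solve(cf, self.c[list(cols)], check_finite=False)

    def rss(self, cols: Sequence[int], beta: np.ndarray | None = None) -> float | None:
        if beta is None:
            beta = self.solve(cols)
            if beta is None:
                return None
        return max(self.yy - float(self.c[list(cols)] @ beta), 0.0)


def _gaussian_aic(rss: float, n: int, n_slopes: int) -> float:
    """AIC of a Gaussian OLS fit; matches statsmodels' OLS ``aic``."""
    rss = max(rss, 1e-300)
    return n * np.log(2 * np.pi) + n * np.log(rss / n) + n + 2 * (n_slopes + 1)


def _eliminate_on_gram(
    gram: _Gram,
    groups: list[tuple[str, list[int]]],
    criterion: str = "aic",
    alpha: float = 0.05,
) -> tuple[list[str], list[tuple[str, float]]] | None:
    """Backward elimination over groups on precomputed sufficient statistics.

    Returns (selected group names, path of (removed group, criterion value
    after removal)), or None if even the full model is singular.
    """
    current = {name: list(idx) for name, idx in groups}

    def cols_of(names):
        out = []
        for nm in names:
            out.extend(current[nm])
        return out

    rss_full = gram.rss(cols_of(current))
    if rss_full is None:
        return None
    n = gram.n

    if criterion == "aic":
        cur_aic = _gaussian_aic(rss_full, n, len(cols_of(current)))
        path: list[tuple[str, float]] = []
        while current:
            best_name, best_aic = None, cur_aic - 1e-9
            for name in sorted(current):
                rest = [nm for nm in current if nm != name]
                rss = gram.rss(cols_of(rest))
                if rss is None:
                    continue
                a = _gaussian_aic(rss, n, len(cols_of(rest)))
                if a < best_aic - 1e-12:
                    best_name, best_aic = name, a
            if best_name is None:
                break
            del current[best_name]
            cur_aic = best_aic
            path.append((best_name, cur_aic))
        order = [g for g, _ in groups]
        return [g for g in order if g in current], path
    elif criterion == "pvalue":
        from scipy.stats import f as f_dist

        path = []
        while current:
            cols_full = cols_of(current)
            rss_with = gram.rss(cols_full)
            if rss_with is None:
                return None
            dfe = n - len(cols_full) - 1
            worst_name, worst_p = None, alpha
            for name in sorted(current):
                rest = [nm for nm in current if nm != name]
                rss_wo = gram.rss(cols_of(rest))
                if rss_wo is None:
                    continue
                q = len(current[name])
                fstat = ((rss_wo - rss_with) / q) / (rss_with / dfe) if rss_with > 0 else np.inf
                p = float(f_dist.sf(fstat, q, dfe))
                if p > worst_p + 1e-12:
                    worst_name, worst_p = name, p
            if worst_name is None:
                break
            del current[worst_name]
            path.append((worst_name, worst_p))
        return list(current), path
    raise UsageError(f"unknown elimination criterion {criterion!r}")


def _normalize_groups(
    X: pd.DataFrame, groups: dict[str, Sequence[str]] | None
) -> list[tuple[str, list[int]]]:
    cols = list(X.columns)
    if groups is None:
        return [(c, [i]) for i, c in enumerate(cols)]
    out: list[tuple[str, list[int]]] = []
    seen: set[str] = set()
    for name, members in groups.items():
        idx = []
        for m in members:
            if m not in cols:
                raise UsageError(f"group {name!r} references missing column {m!r}")
            idx.append(cols.index(m))
            seen.add(m)
        out.append((name, idx))
    for i, c in enumerate(cols):
        if c not in seen and c not in groups:
            out.append((c, [i]))
    if {m for _, idx in out for m in idx} != set(range(len(cols))):
        raise UsageError("groups must partition the design columns")
    return out


def backward_eliminate(
    exog: pd.DataFrame,
    endog: Sequence[float],
    groups: dict[str, Sequence[str]] | None = None,
    criterion: Literal["aic", "pvalue"] = "aic",
    alpha: float = 0.05,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Stepwise backward elimination starting from the full model.

    At each step the group (variable, or dummy block for a categorical)
    whose removal most improves the criterion is dropped; elimination stops
    when no removal improves it.  Deterministic: criterion ties are broken
    by group name.  A perfectly collinear full model is repaired by dropping
    the offending columns first (logged).
    """
    X = pd.DataFrame(exog).astype(float)
    y = np.asarray(endog, dtype=float)
    glist = _normalize_groups(X, groups)
    gram = _Gram(X.to_numpy(), y)
    result = _eliminate_on_gram(gram, glist, criterion, alpha)
    if result is None:
        # repair: drop columns beyond the numerical rank, then retry
        bad = _collinear_columns(gram.Xc, list(X.columns))
        log.warning("full model singular; dropping perfectly collinear columns %s", bad)
        keep_groups = [(n, i) for n, i in glist if not any(X.columns[j] in bad for j in i)]
        result = _eliminate_on_gram(gram, keep_groups, criterion, alpha)
        if result is None:
            raise SingularDesignError(bad, "design remains singular after repair")
    selected, path = result
    order = [name for name, _ in glist]
    return sorted(selected, key=order.index), path


# ---------------------------------------------------------------------------
# BCa confidence intervals
# ---------------------------------------------------------------------------

class BcaInterval(NamedTuple):
    lo: float
    hi: float
    flag: str | None = None


def bca_interval(
    draws: Sequence[float],
    theta_hat: float,
    jackknife_values: Sequence[float],
    alpha: float = 0.05,
) -> BcaInterval:
    """Bias-corrected and accelerated bootstrap interval from given draws.

    The bias correction ``z0`` is the normal quantile of the fraction of
    draws below the full-sample estimate; the acceleration ``a`` comes from
    the skewness of the jackknife (leave-one-out) estimates:

        a = sum(d_i^3) / (6 * (sum(d_i^2))^{3/2}),  d_i = mean(jk) - jk_i.

    The percentile levels alpha/2 and 1-alpha/2 are then shifted through
    ``z0`` and ``a`` before reading off empirical quantiles of the draws.
    With z0 = 0 and a = 0 this reduces exactly to the percentile interval.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2 or np.all(draws == draws[0]):
        val = float(draws[0]) if draws.size else float("nan")
        return BcaInterval(val, val, "degenerate")
    jk = np.asarray(jackknife_values, dtype=float)
    B = draws.size
    flag = None
    count = int(np.sum(draws < theta_hat))
    if count in (0, B):
        prop = (count + 0.5) / (B + 1)
        flag = "z0_clamped"
    else:
        prop = count / B
    z0 = ndtri(prop)
    d = jk.mean() - jk
    ssq = float(np.sum(d**2))
    a = float(np.sum(d**3) / (6.0 * ssq**1.5)) if ssq > 0 else 0.0
    out = []
    for z_alpha in (ndtri(alpha / 2.0), ndtri(1.0 - alpha / 2.0)):
        num = z0 + z_alpha
        level = ndtr(z0 + num / (1.0 - a * num))
        out.append(float(np.quantile(draws, level)))
    lo, hi = min(out), max(out)
    return BcaInterval(lo, hi, flag)


def jackknife_coefficients(exog: pd.DataFrame, endog: Sequence[float]) -> pd.DataFrame:
    """Leave-one-observation-out OLS slope estimates, one row per left-out row.

    Uses the exact downdate formula beta_(i) = beta - (X'X)^-1 x_i e_i/(1-h_i);
    no refitting loop.
    """
    X = pd.DataFrame(exog).astype(float)
    names = list(X.columns)
    design = np.column_stack([np.ones(len(X)), X.to_numpy()])
    y = np.asarray(endog, dtype=float)
    xtx = design.T @ design
    try:
        A = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(names, "jackknife requires a full-rank design") from exc
    beta = A @ design.T @ y
    resid = y - design @ beta
    h = np.einsum("ij,jk,ik->i", design, A, design)
    adjust = (A @ design.T) * (resid / (1.0 - h))
    loo = beta[None, :] - adjust.T
    return pd.DataFrame(loo[:, 1:], columns=names)


# ---------------------------------------------------------------------------
# bootstrap selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Bootstrap-selection output: frequencies, draws, intervals, stable set."""

    variables: list[str]  # group names in candidate order
    group_columns: dict[str, list[str]]  # group -> design columns
    inclusion_frequency: pd.Series  # per group, in [0, 1]
    draws: dict[str, np.ndarray]  # per design column, conditional on selection
    coefficient_median: pd.Series  # per design column (NaN if never selected)
    theta_hat: dict[str, float] = field(default_factory=dict)
    bca: dict[str, BcaInterval] = field(default_factory=dict)
    stable: list[str] | None = None
    threshold: float | None = None
    B: int = 0
    seed: int | None = None
    n_redrawn: int = 0

    @property
    def stable_set(self) -> list[str]:
        if self.stable is None:
            raise UsageError("stable set not computed; run the two-step filter first")
        return list(self.stable)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-design-column summary."""
        rows = []
        for g in self.variables:
            for col in self.group_columns[g]:
                iv = self.bca.get(col)
                rows.append(
                    {
                        "variable": g,
                        "column": col,
                        "inclusion_frequency": float(self.inclusion_frequency[g]),
                        "coefficient_median": float(self.coefficient_median[col]),
                        "theta_hat": self.theta_hat.get(col, np.nan),
                        "bca_lo": iv.lo if iv else np.nan,
                        "bca_hi": iv.hi if iv else np.nan,
                        "bca_flag": iv.flag if iv else None,
                        "stable": (self.stable is not None and g in self.stable),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "B": self.B,
            "seed": self.seed,
            "threshold": self.threshold,
            "n_redrawn": self.n_redrawn,
            "stable_set": self.stable,
            "variables": {
                g: {
                    "inclusion_frequency": float(self.inclusion_frequency[g]),
                    "columns": {
                        col: {
                            "coefficient_median": None
                            if np.isnan(self.coefficient_median[col])
                            else float(self.coefficient_median[col]),
                            "theta_hat": self.theta_hat.get(col),
                            "bca": list(self.bca[col][:2]) if col in self.bca else None,
                            "bca_flag": self.bca[col].flag if col in self.bca else None,
                        }
                        for col in self.group_columns[g]
                    },
                }
                for g in self.variables
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def bootstrap_selection(
    exog: pd.DataFrame,
    endog: Sequence[float],
    B: int = 2000,
    seed: int | None = None,
    groups: dict[str, Sequence[str]] | None = None,
    criterion: str = "aic",
) -> SelectionResult:
    """Repeat backward elimination on ``B`` bootstrap resamples.

    For each resample (drawn with replacement, same size as the data) the
    full elimination is rerun; a variable's inclusion frequency is the
    fraction of resamples in which it survives, and its coefficient draws
    are the fitted coefficients from exactly those resamples.  Resamples
    with a singular full model are redrawn (warned about above a 1% rate).
    Reproducible given ``seed`` via a counter-based seed-spawning scheme.
    """
    if B < 1:
        raise UsageError("B must be >= 1")
    X = pd.DataFrame(exog).astype(float)
    y = np.asarray(endog, dtype=float)
    n = len(y)
    glist = _normalize_groups(X, groups)
    gnames = [g for g, _ in glist]
    cols = list(X.columns)
    Xn = X.to_numpy()
    root = np.random.SeedSequence(seed if seed is not None else 0)
    counts = {g: 0 for g in gnames}
    draws: dict[str, list[float]] = {c: [] for c in cols}
    n_redrawn = 0
    counter = 0
    for _ in range(B):
        while True:
            rng = np.random.default_rng(np.random.SeedSequence(root.entropy, spawn_key=(counter,)))
            counter += 1
            idx = rng.integers(0, n, size=n)
            gram = _Gram(Xn[idx], y[idx])
            result = _eliminate_on_gram(gram, glist, criterion)
            if result is None:
                n_redrawn += 1
                continue
            selected, _ = result
            sel_cols = [j for g, gidx in glist if g in selected for j in gidx]
            beta = gram.solve(sel_cols)
            if beta is None:  # selected submodel singular: redraw too
                n_redrawn += 1
                continue
            break
        for g in selected:
            counts[g] += 1
        for j, b in zip(sel_cols, beta):
            draws[cols[j]].append(float(b))
    if n_redrawn > 0.01 * B:
        warnings.warn(
            f"{n_redrawn} singular bootstrap replicates redrawn (> 1% of B={B})",
            RuntimeWarning,
            stacklevel=2,
        )
    freq = pd.Series({g: counts[g] / B for g in gnames})
    draws_np = {c: np.asarray(v) for c, v in draws.items()}
    median = pd.Series(
        {c: (np.median(v) if v.size else np.nan) for c, v in draws_np.items()}
    )
    return SelectionResult(
        variables=gnames,
        group_columns={g: [cols[j] for j in gidx] for g, gidx in glist},
        inclusion_frequency=freq,
        draws=draws_np,
        coefficient_median=median,
        B=B,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def stable_set(result: SelectionResult, threshold: float = 0.70) -> list[str]:
    """Two-step stable-variable filter.

    Keeps variables whose inclusion frequency *exceeds* the threshold and
    whose BCa interval endpoints share a nonzero sign (for dummy blocks,
    every block column must be sign-consistent).  Intervals touching zero at
    an endpoint are treated as sign-ambiguous and excluded.
    """
    out = []
    for g in result.variables:
        if result.inclusion_frequency[g] <= threshold:
            continue
        intervals = []
        for col in result.group_columns[g]:
            if col not in result.bca:
                raise UsageError(
                    f"no BCa interval for {col!r}; compute intervals for all "
                    "variables passing the frequency filter first"
                )
            intervals.append(result.bca[col])
        ok = all(np.sign(iv.lo) == np.sign(iv.hi) != 0 for iv in intervals)
        if ok:
            out.append(g)
        else:
            log.info("variable %s passed frequency filter but has sign-ambiguous BCa interval", g)
    return out


def select_stable_variables(
    exog: pd.DataFrame,
    endog: Sequence[float],
    B: int = 2000,
    seed: int | None = None,
    threshold: float = 0.70,
    alpha: float = 0.05,
    groups: dict[str, Sequence[str]] | None = None,
    criterion: str = "aic",
    zero_imputation: bool = False,
) -> SelectionResult:
    """Full two-step procedure: bootstrap selection, BCa intervals, sign filter.

    ``zero_imputation=True`` pads a variable's draw distribution with zeros
    for the replicates in which it was not selected (the default uses draws
    conditional on selection).
    """
    result = bootstrap_selection(exog, endog, B=B, seed=seed, groups=groups, criterion=criterion)
    result.threshold = threshold
    passing = [g for g in result.variables if result.inclusion_frequency[g] > threshold]
    if passing:
        pass_cols = [c for g in passing for c in result.group_columns[g]]
        Xsub = pd.DataFrame(exog).astype(float)[pass_cols]
        fit = fit_ols(Xsub, endog)
        jk = jackknife_coefficients(Xsub, endog)
        for col in pass_cols:
            theta = float(fit.params[col])
            result.theta_hat[col] = theta
            d = result.draws[col]
            if zero_imputation and d.size < B:
                d = np.concatenate([d, np.zeros(B - d.size)])
            result.bca[col] = bca_interval(d, theta, jk[col].to_numpy(), alpha=alpha)
    result.stable = stable_set(result, threshold)
    return result


# ---------------------------------------------------------------------------
# design-matrix assembly from a cohort
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Which outcome to model and which candidates may enter selection."""

    outcome: Literal["rfm", "vat", "smi"]
    candidates: tuple[str, ...]
    include_age: bool = False
    include_lifestyle: bool = False
    standardize: bool = False

    def __post_init__(self):
        if self.outcome not in OUTCOME_DESIGN_COLUMNS:
            raise UsageError(f"unknown outcome {self.outcome!r}")
        if not self.candidates and not (self.include_age or self.include_lifestyle):
            raise UsageError("candidate set is empty")


def design_matrix(
    cohort: CohortTable, spec: DesignSpec
) -> tuple[pd.DataFrame, pd.Series, dict[str, tuple[str, ...]]]:
    """Build (X, y, groups) for one outcome from a (single-stratum) cohort.

    Complete cases only; categorical lifestyle covariates are expanded to
    treatment-coded dummies grouped as blocks.  ``standardize`` z-scores the
    continuous columns (coefficients then per-SD).
    """
    enriched = cohort.with_derived_indices()
    df = enriched.data
    df = df[~df["_incomplete"].astype(bool) & ~df["_artefact"].astype(bool)].reset_index(drop=True)
    if df.empty:
        raise UsageError("no complete cases available for model fitting")
    cols: list[str] = []
    groups: dict[str, tuple[str, ...]] = {}
    for name in spec.candidates:
        col = _ALIASES.get(name, name)
        if col not in df.columns:
            raise UsageError(f"candidate variable {name!r} not found in cohort")
        cols.append(col)
        groups[name] = (col,)
    if spec.include_age:
        cols.append("age")
        groups["age"] = ("age",)
    if spec.include_lifestyle:
        df = add_lifestyle_dummies(df)
        for gname, gcols in LIFESTYLE_GROUPS.items():
            cols.extend(gcols)
            groups[gname] = tuple(gcols)
    X = df[cols].astype(float).copy()
    # column names may repeat across aliases; forbid duplicates
    if X.columns.duplicated().any():
        raise UsageError(f"duplicate design columns: {X.columns[X.columns.duplicated()].tolist()}")
    if spec.standardize:
        for c in X.columns:
            sd = X[c].std(ddof=1)
            if sd > 0:
                X[c] = (X[c] - X[c].mean()) / sd
    y = df[OUTCOME_DESIGN_COLUMNS[spec.outcome]].astype(float).rename(spec.outcome)
    # rename design columns to the requested candidate names where aliased
    rename = {v[0]: k for k, v in groups.items() if len(v) == 1 and v[0] != k}
    X = X.rename(columns=rename)
    groups = {k: tuple(rename.get(c, c) for c in v) for k, v in groups.items()}
    return X, y, groups


# ---------------------------------------------------------------------------
# statsmodels-style model / results pair
# ---------------------------------------------------------------------------

class StabilitySelection:
    """Bootstrap-stabilised variable-selection model for one outcome.

    Parameters
    ----------
    endog : array-like
        Outcome vector.
    exog : DataFrame
        Candidate design matrix (no intercept column).
    groups : mapping, optional
        Dummy-block structure; unlisted columns form singleton groups.
    criterion : {"aic", "pvalue"}
        Backward-elimination removal criterion.
    """

    def __init__(
        self,
        endog,
        exog: pd.DataFrame,
        groups: dict[str, Sequence[str]] | None = None,
        criterion: str = "aic",
        zero_imputation: bool = False,
    ):
        self.exog = pd.DataFrame(exog).astype(float)
        self.endog = pd.Series(np.asarray(endog, dtype=float), name=getattr(endog, "name", "y"))
        if len(self.endog) != len(self.exog):
            raise UsageError("endog and exog lengths differ")
        self.groups = groups
        self.criterion = criterion
        self.zero_imputation = zero_imputation

    @classmethod
    def from_cohort(
        cls,
        cohort: CohortTable,
        outcome: str,
        sex: str | None = None,
        candidates: Sequence[str] | None = None,
        include_age: bool = False,
        include_lifestyle: bool = False,
        standardize: bool = False,
        **kwargs,
    ) -> "StabilitySelection":
        if sex is not None:
            cohort = cohort.stratum(sex)
        if candidates is None:
            candidates = tuple(cohort.scan_measures)
        spec = DesignSpec(
            outcome=outcome,
            candidates=tuple(candidates),
            include_age=include_age,
            include_lifestyle=include_lifestyle,
            standardize=standardize,
        )
        X, y, groups = design_matrix(cohort, spec)
        model = cls(y, X, groups=groups, **kwargs)
        model.spec = spec
        return model

    def fit(
        self,
        n_boot: int = 2000,
        threshold: float = 0.70,
        alpha: float = 0.05,
        seed: int | None = None,
    ) -> "StabilitySelectionResults":
        result = select_stable_variables(
            self.exog,
            self.endog,
            B=n_boot,
            seed=seed,
            threshold=threshold,
            alpha=alpha,
            groups=self.groups,
            criterion=self.criterion,
            zero_imputation=self.zero_imputation,
        )
        return StabilitySelectionResults(self, result)


class StabilitySelectionResults:
    """Results of a :class:`StabilitySelection` fit."""

    def __init__(self, model: StabilitySelection, selection: SelectionResult):
        self.model = model
        self.selection = selection
        self._final_fit: ModelFit | None = None

    # -- accessors ----------------------------------------------------------
    @property
    def inclusion_frequency(self) -> pd.Series:
        return self.selection.inclusion_frequency

    @property
    def stable_set(self) -> list[str]:
        return self.selection.stable_set

    @property
    def stable_columns(self) -> list[str]:
        return [c for g in self.stable_set for c in self.selection.group_columns[g]]

    @property
    def params(self) -> pd.Series:
        """Median bootstrapped coefficient per design column."""
        return self.selection.coefficient_median

    def conf_int(self) -> pd.DataFrame:
        """95% BCa intervals for columns that passed the frequency filter."""
        rows = {c: (iv.lo, iv.hi) for c, iv in self.selection.bca.items()}
        return pd.DataFrame.from_dict(rows, orient="index", columns=["lo", "hi"])

    @property
    def final_fit(self) -> ModelFit | None:
        """OLS refit of the stable variables on the full data (None if empty)."""
        if self._final_fit is None and self.stable_set:
            self._final_fit = fit_ols(self.model.exog[self.stable_columns], self.model.endog)
        return self._final_fit

    def predict(self) -> np.ndarray:
        fit = self.final_fit
        if fit is None:
            return np.full(len(self.model.endog), float(self.model.endog.mean()))
        return fit.fittedvalues

    # -- downstream statistics ----------------------------------------------
    def validate(self, iterations: int = 2000, seed: int | None = None):
        """Bootstrap out-of-bag validation of the stable-variable model."""
        from .evaluate import bootstrap_validate

        return bootstrap_validate(
            self.model.exog[self.stable_columns], self.model.endog, iterations, seed
        )

    def bland_altman(self):
        """Agreement between measured outcome and stable-model predictions."""
        from .evaluate import bland_altman

        return bland_altman(self.model.endog.to_numpy(), self.predict())

    def plot_bland_altman(self, ax=None):
        from .evaluate import plot_bland_altman

        return plot_bland_altman(self.model.endog.to_numpy(), self.predict(), ax=ax)

    def summary(self) -> str:
        """Human-readable selection summary table."""
        sel = self.selection
        lines = [
            "Bootstrap stability selection",
            f"  replicates B = {sel.B}, seed = {sel.seed}, threshold = {sel.threshold}",
            f"  candidates = {len(sel.variables)}, stable set = {len(sel.stable or [])}",
            "",
            f"  {'variable':<32}{'freq':>7}{'median':>10}{'BCa lo':>10}{'BCa hi':>10}  stable",
        ]
        for g in sorted(sel.variables, key=lambda g: -sel.inclusion_frequency[g]):
            for col in sel.group_columns[g]:
                iv = sel.bca.get(col)
                med = sel.coefficient_median[col]
                med_s = f"{med:>10.3f}" if not np.isnan(med) else f"{'--':>10}"
                tail = f"{iv.lo:>10.3f}{iv.hi:>10.3f}" if iv is not None else f"{'--':>10}{'--':>10}"
                mark = "  *" if (sel.stable and g in sel.stable) else ""
                lines.append(
                    f"  {col:<32}{sel.inclusion_frequency[g]:>7.3f}{med_s}{tail}{mark}"
                )
        return "\n".join(lines)
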