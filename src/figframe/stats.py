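"""Covariate-adjusted cohort comparisons of descriptor tables.

The central model is an ANCOVA: a linear model
``outcome ~ 1 + covariates + group`` for a two-level group factor.  With a
single-df effect the Type III (marginal) group F equals the squared t of
the group coefficient in the full model, and

* partial eta squared = SS_group / (SS_group + SS_residual)
  = F / (F + df_residual),
* the adjusted difference is the group coefficient (adjusted mean of the
  second level minus the first, levels sorted),
* Cohen's d is the adjusted difference over the residual SD.

Post-hoc uncertainty comes from a stratified bootstrap: subjects are
resampled with replacement within groups, the model refit, and the
percentile CI of the adjusted difference reported.  Bonferroni correction
multiplies p by an explicit family size m.

Model fits go through statsmodels OLS; the bootstrap uses a plain
least-squares refit of the identical design matrix for speed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import Paradigm, TASK_PARADIGMS, CALIBRATION_PARADIGMS

__all__ = [
    "AncovaResult",
    "CorrelationResult",
    "ComparisonPlan",
    "CollinearityError",
    "PlanError",
    "ancova",
    "bootstrap_posthoc",
    "bonferroni",
    "correlate",
    "compare_cohort",
    "sex_area_plan",
    "cognition_plan",
    "load_plan",
]

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20231122


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


class PlanError(ValueError):
    """A comparison plan references data that is not there."""


@dataclass
class AncovaResult:
    """One covariate-adjusted two-group comparison."""

    F: float
    df_effect: int
    df_resid: int
    p: float
    partial_eta_sq: float
    adjusted_difference: float
    cohens_d: float
    t: float
    se: float
    n: int
    group_levels: tuple[str, str]
    p_bonf: float | None = None
    bootstrap_ci: tuple[float, float] | None = None
    n_boot: int = 0
    n_boot_dropped: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    rho: float
    p: float
    n: int
    reason: str = ""


def _design(
    outcome,
    group,
    covariates=None,
    covariate_names: Sequence[str] | None = None,
):
    y = np.asarray(outcome, float)
    g = np.asarray(group)
    if y.ndim != 1 or g.shape != y.shape:
        raise ValueError("outcome and group must be equal-length 1-d vectors")
    levels = tuple(sorted(map(str, set(g.tolist()))))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    indicator = (g.astype(str) == levels[1]).astype(float)
    cols = [np.ones_like(y)]
    names = ["intercept"]
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != y.size:
            raise ValueError("covariates must have one row per observation")
        for j in range(C.shape[1]):
            cols.append(C[:, j])
            names.append(
                covariate_names[j]
                if covariate_names is not None
                else f"covariate_{j}"
            )
    cols.append(indicator)
    names.append("group")
    X = np.column_stack(cols)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("outcome/covariates contain non-finite values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify a column whose removal restores full rank
        for j in range(1, X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
                raise CollinearityError(
                    f"design matrix rank deficient: column {names[j]!r} is"
                    " collinear with the others"
                )
        raise CollinearityError("design matrix rank deficient")
    return y, X, names, levels, indicator


def ancova(
    outcome,
    group,
    covariates=None,
    covariate_names: Sequence[str] | None = None,
    d_method: str = "residual",
) -> AncovaResult:
    """Two-group comparison adjusted for numeric covariates.

    With no covariates this reduces exactly to the one-way two-group
    ANOVA (``F = t**2`` and identical p).  ``d_method="residual"``
    (default) divides the adjusted difference by the residual SD of the
    full model; ``"pooled"`` uses the pooled raw within-group SD instead.
    """
    y, X, names, levels, indicator = _design(
        outcome, group, covariates, covariate_names
    )
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations, got {n}")
    res = sm.OLS(y, X).fit()
    df_resid = int(res.df_resid)
    t = float(res.tvalues[-1])
    beta = float(res.params[-1])
    se = float(res.bse[-1])
    F = t * t
    p = float(res.pvalues[-1])
    eta = F / (F + df_resid) if math.isfinite(F) else float("nan")
    mse = res.ssr / df_resid
    if d_method == "residual":
        d = beta / math.sqrt(mse) if mse > 0 else float("nan")
    elif d_method == "pooled":
        g1 = y[indicator == 1.0]
        g0 = y[indicator == 0.0]
        sp2 = (
            (len(g0) - 1) * g0.var(ddof=1) + (len(g1) - 1) * g1.var(ddof=1)
        ) / (len(g0) + len(g1) - 2)
        d = (g1.mean() - g0.mean()) / math.sqrt(sp2) if sp2 > 0 else float("nan")
    else:
        raise ValueError(f"unknown d_method {d_method!r}")
    return AncovaResult(
        F=F,
        df_effect=1,
        df_resid=df_resid,
        p=p,
        partial_eta_sq=eta,
        adjusted_difference=beta,
        cohens_d=d,
        t=t,
        se=se,
        n=n,
        group_levels=levels,
    )


@dataclass(frozen=True)
class BootstrapResult:
    ci_low: float
    ci_high: float
    n_boot: int
    n_dropped: int
    seed: int
    estimates: np.ndarray = field(repr=False, default=None)


def bootstrap_posthoc(
    outcome,
    group,
    covariates=None,
    n_boot: int = 1000,
    seed: int = DEFAULT_SEED,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap CI for the adjusted group difference.

    Subjects are resampled with replacement *within* groups (the group
    sizes are fixed by design), the linear model refit per replicate and
    the percentile interval of the group coefficient taken.  Replicates
    with a rank-deficient design are dropped and counted; losing more
    than 20% triggers a warning.  Deterministic given ``seed``.
    """
    y, X, names, levels, indicator = _design(outcome, group, covariates)
    rng = np.random.default_rng(seed)
    idx0 = np.nonzero(indicator == 0.0)[0]
    idx1 = np.nonzero(indicator == 1.0)[0]
    k = X.shape[1]
    estimates = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx0, size=len(idx0)), rng.choice(idx1, size=len(idx1))]
        )
        Xb, yb = X[take], y[take]
        beta, _, rank, _ = np.linalg.lstsq(Xb, yb, rcond=None)
        if rank < k:
            continue
        estimates[kept] = beta[-1]
        kept += 1
    dropped = n_boot - kept
    if n_boot and dropped > 0.2 * n_boot:
        warnings.warn(
            f"bootstrap dropped {dropped}/{n_boot} rank-deficient replicates",
            RuntimeWarning,
        )
    est = estimates[:kept]
    alpha = (1.0 - ci_level) / 2.0
    if kept == 0:
        lo = hi = float("nan")
    else:
        lo, hi = np.percentile(est, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapResult(float(lo), float(hi), n_boot, dropped, seed, est)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values: ``min(1, p * m)`` elementwise."""
    p = np.atleast_1d(np.asarray(p_values, float))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, p * m)


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with the t-approximation p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(
            method, float("nan"), float("nan"), x.size, "zero-variance-input"
        )
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method, float(r.statistic), float(r.pvalue), x.size)


# ---------------------------------------------------------------------------
# comparison plans


@dataclass(frozen=True)
class ComparisonPlan:
    """A family of covariate-adjusted group comparisons.

    One plan compares ``group`` levels on each ``outcome`` descriptor, in
    each listed paradigm and (optionally) on the per-subject mean over the
    task paradigms (the *overall average* outcome).  ``meta_covariates``
    name subject-table columns; ``calibration_covariates`` are
    ``(descriptor, paradigm)`` pairs whose per-subject value is entered as
    a covariate — the device-calibration adjustment for anatomical
    confounders (shoulder width, arm length).  ``m`` is the explicit
    Bonferroni family size; by default the number of contrasts per
    outcome family.
    """

    name: str
    group: str
    outcomes: tuple[str, ...]
    paradigms: tuple[Paradigm, ...] = TASK_PARADIGMS
    include_overall: bool = True
    meta_covariates: tuple[str, ...] = ()
    calibration_covariates: tuple[tuple[str, Paradigm], ...] = ()
    subset: tuple[tuple[str, str], ...] = ()
    m: int | None = None
    n_boot: int = 1000
    d_method: str = "residual"

    @property
    def family_size(self) -> int:
        return self.m or (len(self.paradigms) + (1 if self.include_overall else 0))


def sex_area_plan(n_boot: int = 1000) -> ComparisonPlan:
    """Female vs male frame area, adjusted for age, normal cognition only.

    All seven paradigms enter individually (the sex difference is already
    present in the calibrations, so calibrations are outcomes here, not
    covariates)."""
    return ComparisonPlan(
        name="sex_area",
        group="sex",
        outcomes=("area_px",),
        paradigms=CALIBRATION_PARADIGMS + TASK_PARADIGMS,
        include_overall=False,
        meta_covariates=("age_years",),
        subset=(("cognition", "normal"),),
        n_boot=n_boot,
    )


def cognition_plan(
    outcomes: tuple[str, ...] = ("avg_diameter_px", "solidity", "area_px"),
    n_boot: int = 1000,
) -> ComparisonPlan:
    """Normal vs impaired cognition on the five task paradigms.

    Adjusted for age and for the subject's world-based and retinotopic
    calibration frame areas (sexes pooled; the calibration areas absorb
    the anatomical/sex size differences)."""
    return ComparisonPlan(
        name="cognition",
        group="cognition",
        outcomes=outcomes,
        paradigms=TASK_PARADIGMS,
        include_overall=True,
        meta_covariates=("age_years",),
        calibration_covariates=(
            ("area_px", Paradigm.WORLD_CALIBRATION),
            ("area_px", Paradigm.RETINOTOPIC_CALIBRATION),
        ),
        n_boot=n_boot,
    )


def load_plan(path: str | Path) -> ComparisonPlan:
    """Read a plan from a YAML or JSON mapping mirroring ComparisonPlan."""
    import json

    import yaml

    text = Path(path).read_text()
    doc = (
        json.loads(text)
        if str(path).endswith(".json")
        else yaml.safe_load(text)
    )
    if not isinstance(doc, dict):
        raise PlanError(f"{path}: expected a mapping")
    kwargs = dict(doc)
    if "paradigms" in kwargs:
        kwargs["paradigms"] = tuple(Paradigm(p) for p in kwargs["paradigms"])
    if "calibration_covariates" in kwargs:
        kwargs["calibration_covariates"] = tuple(
            (o, Paradigm(p)) for o, p in kwargs["calibration_covariates"]
        )
    for key in ("outcomes", "meta_covariates"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "subset" in kwargs:
        kwargs["subset"] = tuple((k, v) for k, v in dict(kwargs["subset"]).items())
    try:
        return ComparisonPlan(**kwargs)
    except TypeError as exc:
        raise PlanError(f"{path}: {exc}") from None


def _subject_outcome_table(
    descriptors: pd.DataFrame, outcome: str, paradigms: Sequence[Paradigm]
) -> pd.DataFrame:
    wide = descriptors.pivot_table(
        index="subject_id", columns="paradigm", values=outcome, aggfunc="first"
    )
    for p in paradigms:
        if p.value not in wide.columns:
            raise PlanError(f"paradigm {p.value!r} absent from descriptor table")
    return wide


def compare_cohort(
    descriptors: pd.DataFrame,
    meta: pd.DataFrame,
    plan: ComparisonPlan,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Run one comparison plan over a descriptor table.

    Returns one row per outcome x contrast (each listed paradigm, plus
    the ``overall`` mean of the plan's paradigms when enabled) with F,
    dfs, p, Bonferroni-adjusted p, partial eta squared, the adjusted
    difference with its bootstrap CI, Cohen's d and t.  Subjects with
    missing covariate or outcome values are dropped with a log entry.
    """
    for col in ("subject_id", "paradigm") + tuple(plan.outcomes):
        if col not in descriptors.columns:
            raise PlanError(f"descriptor table lacks column {col!r}")
    needed_meta = {plan.group, *plan.meta_covariates, *(k for k, _ in plan.subset)}
    for col in needed_meta | {"subject_id"}:
        if col not in meta.columns:
            raise PlanError(f"meta table lacks column {col!r}")
    meta_idx = meta.set_index("subject_id")
    orphans = set(descriptors["subject_id"]) - set(meta_idx.index)
    if orphans:
        raise PlanError(
            f"descriptor subjects missing from meta: {sorted(orphans)[:5]}"
        )

    keep = meta_idx
    for key, value in plan.subset:
        keep = keep[keep[key].astype(str) == str(value)]

    calib_cols: dict[str, pd.Series] = {}
    for outcome, paradigm in plan.calibration_covariates:
        wide = _subject_outcome_table(descriptors, outcome, [paradigm])
        calib_cols[f"{outcome}@{paradigm.value}"] = wide[paradigm.value]

    rows = []
    boot_seq = np.random.SeedSequence(seed)
    for outcome in plan.outcomes:
        wide = _subject_outcome_table(descriptors, outcome, plan.paradigms)
        contrasts: list[tuple[str, pd.Series]] = [
            (p.value, wide[p.value]) for p in plan.paradigms
        ]
        if plan.include_overall:
            overall = wide[[p.value for p in plan.paradigms]].mean(axis=1)
            contrasts.append(("overall", overall))
        m = plan.m or len(contrasts)
        for contrast_name, series in contrasts:
            df = pd.DataFrame({"outcome": series})
            df["group"] = keep[plan.group]
            for cov in plan.meta_covariates:
                df[cov] = keep[cov]
            for cname, cseries in calib_cols.items():
                df[cname] = cseries
            df = df.loc[df.index.isin(keep.index)]
            n_before = len(df)
            df = df.dropna()
            if len(df) < n_before:
                logger.info(
                    "%s/%s/%s: dropped %d subjects with missing values",
                    plan.name,
                    outcome,
                    contrast_name,
                    n_before - len(df),
                )
            cov_names = list(plan.meta_covariates) + list(calib_cols)
            cov_matrix = df[cov_names].to_numpy() if cov_names else None
            res = ancova(
                df["outcome"].to_numpy(),
                df["group"].to_numpy(),
                cov_matrix,
                covariate_names=cov_names,
                d_method=plan.d_method,
            )
            res.p_bonf = float(bonferroni([res.p], m)[0])
            child_seed = int(boot_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            if plan.n_boot > 0:
                boot = bootstrap_posthoc(
                    df["outcome"].to_numpy(),
                    df["group"].to_numpy(),
                    cov_matrix,
                    n_boot=plan.n_boot,
                    seed=child_seed,
                )
                res.bootstrap_ci = (boot.ci_low, boot.ci_high)
                res.n_boot = boot.n_boot
                res.n_boot_dropped = boot.n_dropped
                res.seed = child_seed
            rows.append(
                {
                    "plan": plan.name,
                    "outcome": outcome,
                    "contrast": contrast_name,
                    "group": plan.group,
                    "level_low": res.group_levels[0],
                    "level_high": res.group_levels[1],
                    "n": res.n,
                    "F": res.F,
                    "df_effect": res.df_effect,
                    "df_resid": res.df_resid,
                    "p": res.p,
                    "p_bonf": res.p_bonf,
                    "m": m,
                    "partial_eta_sq": res.partial_eta_sq,
                    "adjusted_difference": res.adjusted_difference,
                    "ci_low": res.bootstrap_ci[0] if res.bootstrap_ci else np.nan,
                    "ci_high": res.bootstrap_ci[1] if res.bootstrap_ci else np.nan,
                    "cohens_d": res.cohens_d,
                    "t": res.t,
                    "n_boot": res.n_boot,
                    "n_boot_dropped": res.n_boot_dropped,
                }
            )
    return pd.DataFrame(rows)
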