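"""Cohort statistics: Box-Cox normalisation, region x group ANOVA with
partial eta-squared effect sizes, and baseline group tests.

The analysis stage mirrors a two-factor design with factors
*lesion compartment* (DWI lesion vs. tissue at risk) and *group*
(MCA occlusion alone vs. occlusion with carotid stenosis).  Each of the
five VOI parameters (ADC, Tmax, CBF, CBV, MTT) is Box-Cox transformed
towards normality when a Shapiro-Wilk test rejects at alpha = 0.05, then
decomposed into sums of squares for compartment, group and their
interaction.  Effect sizes are partial eta^2 = SS_effect / (SS_effect +
SS_error), classified as negligible / small / moderate / large at the
0.04 / 0.25 / 0.64 thresholds (Ferguson's recommendations).

An omnibus multivariate statistic (Pillai's trace across all five
parameters) can be reported alongside the per-parameter tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

EFFECT_THRESHOLDS = (0.04, 0.25, 0.64)   # small / moderate / large
FACTOR_NAMES = ("lesion_compartment", "group", "interaction")


# ---------------------------------------------------------------------------
# Box-Cox

@dataclass
class BoxCoxResult:
    lambda_hat: float
    transformed: np.ndarray
    loglik_profile: np.ndarray   # (n_lambda, 2) columns (lambda, loglik)
    shift: float = 0.0           # added to the data before transforming


def _boxcox_apply(x: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-12:
        return np.log(x)
    return (x ** lam - 1.0) / lam


def _profile_loglik(x: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Vectorised Box-Cox profile log-likelihood over a lambda grid."""
    n = x.size
    logx = np.log(x)
    sum_logx = logx.sum()
    out = np.empty(lambdas.size)
    for i, lam in enumerate(lambdas):
        y = _boxcox_apply(x, lam)
        var = y.var()  # MLE variance
        out[i] = (lam - 1.0) * sum_logx - 0.5 * n * np.log(var)
    return out


def box_cox_transform(values, lambda_range: tuple[float, float] = (-3.0, 3.0),
                      step: float = 0.01) -> BoxCoxResult:
    """Box-Cox power transform with lambda from profile-likelihood search.

    The grid maximum over ``lambda_range`` (step 0.01) is refined by a
    bounded golden-section search inside the bracketing grid cell.
    Non-positive data are shifted by ``-min + eps`` first; the shift is
    recorded in the result.  Constant input is rejected (degenerate
    likelihood).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 5:
        raise ValueError("Box-Cox transform needs at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input: Box-Cox likelihood is degenerate")
    shift = 0.0
    if x.min() <= 0:
        shift = -x.min() + 1e-6 * max(np.ptp(x), 1.0)
        x = x + shift
    # round so grid points like 0 are hit exactly (arange accumulates error)
    lambdas = np.round(np.arange(lambda_range[0], lambda_range[1] + step / 2,
                                 step), 10)
    profile = _profile_loglik(x, lambdas)
    i_best = int(np.argmax(profile))
    lo = lambdas[max(i_best - 1, 0)]
    hi = lambdas[min(i_best + 1, lambdas.size - 1)]
    res = minimize_scalar(lambda l: -_profile_loglik(x, np.array([l]))[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(res.x)
    return BoxCoxResult(lambda_hat=lam, transformed=_boxcox_apply(x, lam),
                        loglik_profile=np.column_stack([lambdas, profile]),
                        shift=shift)


# ---------------------------------------------------------------------------
# Two-way ANOVA with partial eta^2

@dataclass
class EffectSizeReport:
    parameter: str
    factor: str            # lesion_compartment | group | interaction
    ss: float
    df: int
    f_value: float
    p_value: float
    partial_eta_sq: float
    size_class: str = field(init=False)

    def __post_init__(self) -> None:
        self.size_class = classify_effect(self.partial_eta_sq)


def classify_effect(partial_eta_sq: float) -> str:
    """Ferguson's effect-size labels at 0.04 / 0.25 / 0.64."""
    v = float(partial_eta_sq)
    if not 0.0 <= v <= 1.0:
        raise ValueError("partial eta^2 must lie in [0, 1]")
    small, moderate, large = EFFECT_THRESHOLDS
    if v >= large:
        return "large"
    if v >= moderate:
        return "moderate"
    if v >= small:
        return "small"
    return "negligible"


def _balanced_two_way_ss(y: np.ndarray, region: np.ndarray,
                         group: np.ndarray):
    """Closed-form SS decomposition for an equal-cell-count design."""
    regions = np.unique(region)
    groups = np.unique(group)
    grand = y.mean()
    n_cell = y.size // (regions.size * groups.size)
    ss_region = sum(((y[region == r].mean() - grand) ** 2) * (y.size // regions.size)
                    for r in regions)
    ss_group = sum(((y[group == g].mean() - grand) ** 2) * (y.size // groups.size)
                   for g in groups)
    ss_inter = 0.0
    ss_err = 0.0
    for r in regions:
        for g in groups:
            cell = y[(region == r) & (group == g)]
            dev = cell.mean() - y[region == r].mean() - y[group == g].mean() + grand
            ss_inter += n_cell * dev ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    df = {
        "lesion_compartment": regions.size - 1,
        "group": groups.size - 1,
        "interaction": (regions.size - 1) * (groups.size - 1),
        "error": y.size - regions.size * groups.size,
    }
    ss = {"lesion_compartment": float(ss_region), "group": float(ss_group),
          "interaction": float(ss_inter), "error": float(ss_err)}
    return ss, df


def _unbalanced_two_way_ss(y, region, group):
    """Type-II SS via statsmodels OLS (used when cell counts differ)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df_in = pd.DataFrame({"y": y, "region": region, "group": group})
    fit = smf.ols("y ~ C(region) * C(group)", data=df_in).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    ss = {
        "lesion_compartment": float(table.loc["C(region)", "sum_sq"]),
        "group": float(table.loc["C(group)", "sum_sq"]),
        "interaction": float(table.loc["C(region):C(group)", "sum_sq"]),
        "error": float(table.loc["Residual", "sum_sq"]),
    }
    dof = {
        "lesion_compartment": int(table.loc["C(region)", "df"]),
        "group": int(table.loc["C(group)", "df"]),
        "interaction": int(table.loc["C(region):C(group)", "df"]),
        "error": int(table.loc["Residual", "df"]),
    }
    return ss, dof


def two_way_anova_eta(cohort: pd.DataFrame, parameter: str,
                      transform: str | None = "auto",
                      region_col: str = "voi", group_col: str = "group"
                      ) -> list[EffectSizeReport]:
    """Region x group ANOVA of one parameter with partial eta^2 per factor.

    ``transform`` is ``"auto"`` (Box-Cox applied when Shapiro-Wilk rejects
    normality at alpha = 0.05), ``"boxcox"`` (always) or ``None`` (never).
    Balanced designs use the exact cell-mean decomposition; unbalanced
    ones fall back to Type-II sums of squares.  Any empty cell is an
    error naming the cell.
    """
    sub = cohort[[region_col, group_col, parameter]].dropna()
    region = sub[region_col].to_numpy()
    group = sub[group_col].to_numpy()
    y = sub[parameter].to_numpy(dtype=float)

    counts = sub.groupby([region_col, group_col]).size()
    for r in np.unique(region):
        for g in np.unique(group):
            if (r, g) not in counts.index:
                raise ValueError(f"empty cell ({region_col}={r}, {group_col}={g})")

    if transform == "boxcox" or (
            transform == "auto" and sps.shapiro(y).pvalue < 0.05):
        y = box_cox_transform(y).transformed
    elif transform not in (None, "auto", "boxcox"):
        raise ValueError(f"unknown transform {transform!r}")

    balanced = counts.nunique() == 1
    ss, dof = (_balanced_two_way_ss if balanced else _unbalanced_two_way_ss)(
        y, region, group)
    ms_err = ss["error"] / dof["error"]
    reports = []
    for factor in FACTOR_NAMES:
        f_val = (ss[factor] / dof[factor]) / ms_err if ms_err > 0 else np.inf
        p = float(sps.f.sf(f_val, dof[factor], dof["error"]))
        eta = ss[factor] / (ss[factor] + ss["error"]) if (
            ss[factor] + ss["error"]) > 0 else 0.0
        reports.append(EffectSizeReport(parameter=parameter, factor=factor,
                                        ss=ss[factor], df=dof[factor],
                                        f_value=float(f_val), p_value=p,
                                        partial_eta_sq=float(eta)))
    return reports


def pillai_trace(cohort: pd.DataFrame, parameters: list[str],
                 region_col: str = "voi", group_col: str = "group") -> dict:
    """Omnibus multivariate (MANOVA) Pillai trace per factor."""
    from statsmodels.multivariate.manova import MANOVA

    sub = cohort[[region_col, group_col] + parameters].dropna().copy()
    sub.columns = ["region", "grp"] + [f"p{i}" for i in range(len(parameters))]
    lhs = " + ".join(f"p{i}" for i in range(len(parameters)))
    mv = MANOVA.from_formula(f"{lhs} ~ C(region) * C(grp)", data=sub)
    res = mv.mv_test()
    out = {}
    for key, factor in (("C(region)", "lesion_compartment"),
                        ("C(grp)", "group"),
                        ("C(region):C(grp)", "interaction")):
        tab = res.results[key]["stat"]
        out[factor] = {"pillai_trace": float(tab.loc["Pillai's trace", "Value"]),
                       "p_value": float(tab.loc["Pillai's trace", "Pr > F"])}
    return out


# ---------------------------------------------------------------------------
# Baseline group tests

def baseline_tests(table: pd.DataFrame, variable: str, var_type: str,
                   group_col: str = "group") -> dict:
    """Two-sided group comparison matched to the variable's scale.

    ``var_type``: ``interval_normal`` -> Student's t-test,
    ``interval_nonnormal`` -> Mann-Whitney U, ``nominal`` -> Fisher's
    exact test on the 2x2 contingency table.  Nominal p-values are
    reported without multiplicity correction.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError("baseline tests expect exactly two groups")
    if var_type == "interval_normal":
        a = table.loc[table[group_col] == groups[0], variable].dropna()
        b = table.loc[table[group_col] == groups[1], variable].dropna()
        stat, p = sps.ttest_ind(a, b)
        test = "student_t"
    elif var_type == "interval_nonnormal":
        a = table.loc[table[group_col] == groups[0], variable].dropna()
        b = table.loc[table[group_col] == groups[1], variable].dropna()
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney_u"
    elif var_type == "nominal":
        contingency = pd.crosstab(table[group_col], table[variable])
        if contingency.shape != (2, 2):
            raise ValueError("Fisher's exact test needs a 2x2 table")
        stat, p = sps.fisher_exact(contingency.to_numpy())
        test = "fisher_exact"
    else:
        raise ValueError(f"unknown variable type {var_type!r}")
    return {"variable": variable, "test": test, "statistic": float(stat),
            "p_value": float(p)}


# ---------------------------------------------------------------------------
# Cohort-level report and synthetic cohort tables

def analyze_cohort(cohort: pd.DataFrame, parameters: list[str] | None = None,
                   transform: str | None = "auto",
                   include_pillai: bool = True) -> dict:
    """Per-parameter effect-size report plus the optional omnibus trace."""
    from .voi import PARAMETERS

    parameters = parameters or [p for p in PARAMETERS if p in cohort.columns]
    report: dict = {"parameters": {}}
    for param in parameters:
        y = cohort[param].dropna().to_numpy(dtype=float)
        entry: dict = {}
        needs_transform = transform == "boxcox" or (
            transform == "auto" and sps.shapiro(y).pvalue < 0.05)
        if needs_transform:
            bc = box_cox_transform(y)
            entry["box_cox"] = {"lambda_hat": bc.lambda_hat, "shift": bc.shift}
        entry["transform_applied"] = bool(needs_transform)
        effects = two_way_anova_eta(cohort, param, transform=transform)
        entry["effects"] = [
            {"factor": e.factor, "ss": e.ss, "df": e.df, "F": e.f_value,
             "p_value": e.p_value, "partial_eta_sq": e.partial_eta_sq,
             "size_class": e.size_class}
            for e in effects]
        report["parameters"][param] = entry
    if include_pillai and len(parameters) > 1:
        try:
            report["pillai"] = pillai_trace(cohort, parameters)
        except Exception as exc:  # degenerate designs: keep the univariate part
            report["pillai"] = {"error": str(exc)}
    return report


def format_effect_table(report: dict) -> str:
    """Human-readable effect-size table (parameter x factor)."""
    lines = [f"{'Parameter':<14}{'Compartment':>24}{'Group':>24}{'Interaction':>24}"]
    for param, entry in report["parameters"].items():
        by = {e["factor"]: e for e in entry["effects"]}
        cells = []
        for fac in FACTOR_NAMES:
            e = by[fac]
            cells.append(f"eta2={e['partial_eta_sq']:.2f} (p={e['p_value']:.3f})")
        lines.append(f"{param:<14}{cells[0]:>24}{cells[1]:>24}{cells[2]:>24}")
    return "\n".join(lines)


# reference VOI medians used by the synthetic cohort table generator
# (DWI lesion vs. TAR compartments of an M1-occlusion cohort)
_REFERENCE_MEDIANS = {
    "dwi_lesion": {"adc_median": 470e-6, "tmax_median": 14.0,
                   "cbf_median": 11.0, "cbv_median": 2.1, "mtt_median": 13.9},
    "tar": {"adc_median": 830e-6, "tmax_median": 11.5,
            "cbf_median": 21.0, "cbv_median": 3.8, "mtt_median": 12.5},
}


def group_factor_for_eta(eta_sq: float, sigma: float = 0.25) -> float:
    """Multiplicative group offset giving an expected partial eta^2.

    For log-normal responses with log-scale sd ``sigma`` and a balanced
    two-group design, a group log-offset delta has expected partial
    eta^2 of (delta^2/4) / (delta^2/4 + sigma^2); invert for delta.
    """
    if not 0 < eta_sq < 1:
        raise ValueError("eta_sq must lie in (0, 1)")
    delta = 2.0 * sigma * np.sqrt(eta_sq / (1.0 - eta_sq))
    return float(np.exp(delta))


def simulate_cohort(n_per_group: int = 16, rng=None,
                    group_effects: dict[str, float] | None = None,
                    sigma: float = 0.25) -> pd.DataFrame:
    """Synthetic subject-level VOI table for statistical simulations.

    Each subject contributes one DWI-lesion and one TAR row; parameter
    values are log-normal around compartment-typical medians with
    log-scale sd ``sigma``.  ``group_effects`` multiplies the named
    parameters in the second group (stenosis-like CBV elevation, for
    example).  Volumes are log-normal around 8 ml (lesion) and 60 ml
    (TAR).
    """
    from .voi import COHORT_COLUMNS

    rng = np.random.default_rng(rng)
    group_effects = group_effects or {}
    rows = []
    for gi, group in enumerate(("M1", "M1_ICA")):
        for si in range(n_per_group):
            sid = f"{group}_{si:02d}"
            for voi, ref in _REFERENCE_MEDIANS.items():
                row = {"subject_id": sid, "group": group, "voi": voi,
                       "volume_ml": float(
                           (8.0 if voi == "dwi_lesion" else 60.0)
                           * rng.lognormal(0.0, 0.5))}
                for param, med in ref.items():
                    val = med * rng.lognormal(0.0, sigma)
                    if gi == 1 and param in group_effects:
                        val *= group_effects[param]
                    row[param] = val
                rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
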