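"""Control normalization, stiffness-regime split and the statistical battery.

Every experimental jump is expressed relative to the mean of that animal's
own control (rigid-surface) jumps: as a proportion for every variable except
elevation, which is a polar quantity and is therefore expressed as a
difference in degrees.  Jumps are then split into two regimes by comparing
the platform stiffness at the jumping line with the across-animal mean
effective jumper stiffness: *compliant* (k_p < mean k_g) and *stiff*
(k_p ≥ mean k_g).

Two families of test are run:

* a two-sided one-sample t-test of each variable at each platform line
  against 1.0 (0.0 for elevation), with a Shapiro normality check and a
  Wilcoxon signed-rank fallback reported alongside when normality fails;
* per-regime linear mixed-effects models with platform stiffness as a
  covariate (plus platform type and an initial stiffness×type interaction in
  the stiff regime, dropped when non-significant) and a per-animal random
  intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import DomainError, ValidationError

__all__ = [
    "RATIO_VARIABLES",
    "DIFFERENCE_VARIABLES",
    "control_means",
    "mean_grasshopper_stiffness",
    "normalize_jumps",
    "assign_regime",
    "OneSampleTestResult",
    "one_sample_test",
    "RegimeModel",
    "RegimeModelResults",
    "regime_model_report",
    "one_sample_report",
]

#: Variables normalized as proportions of the per-animal control mean.
RATIO_VARIABLES = [
    "time_to_takeoff",
    "velocity",
    "acceleration",
    "kinetic_energy",
    "kinetic_energy_density",
    "power",
    "power_density",
]

#: Variables normalized as differences from the per-animal control mean.
DIFFERENCE_VARIABLES = ["elevation"]

NORMALIZED_VARIABLES = RATIO_VARIABLES + DIFFERENCE_VARIABLES


def control_means(jumps: pd.DataFrame) -> pd.DataFrame:
    """Per-animal means of every normalized variable over control jumps only.

    Raises if any animal in the table has no control jumps — normalization
    is undefined for it.
    """
    controls = jumps[jumps["platform_id"] == "control"]
    missing = sorted(set(jumps["animal_id"]) - set(controls["animal_id"]))
    if missing:
        raise ValidationError(f"no control jumps for animal(s): {missing}")
    cols = [c for c in NORMALIZED_VARIABLES + ["k_g"] if c in jumps.columns]
    return controls.groupby("animal_id")[cols].mean()


def mean_grasshopper_stiffness(jumps: pd.DataFrame) -> float:
    """Across-animal mean of per-animal control-jump k_g means."""
    return float(control_means(jumps)["k_g"].mean())


def assign_regime(k_p: float, mean_k_g: float) -> str:
    """Regime label: 'compliant' when k_p < mean k_g, else 'stiff'.

    A platform exactly as stiff as the jumper is labelled stiff (ties on
    the strict-inequality split are resolved upward).
    """
    return "compliant" if k_p < mean_k_g else "stiff"


def normalize_jumps(
    jumps: pd.DataFrame,
    *,
    controls: pd.DataFrame | None = None,
    mean_k_g: float | None = None,
) -> pd.DataFrame:
    """Normalize experimental jumps to per-animal control means.

    Returns one row per experimental jump with identity columns, ``k_p``,
    a ``regime`` label, ratio columns for every variable in
    :data:`RATIO_VARIABLES` and a difference column for elevation.
    """
    if controls is None:
        controls = control_means(jumps)
    if mean_k_g is None:
        mean_k_g = float(controls["k_g"].mean())
    exp = jumps[jumps["platform_id"] != "control"].copy()
    if exp["k_p"].isna().any():
        bad = exp.loc[exp["k_p"].isna(), "animal_id"].tolist()
        raise ValidationError(f"experimental jumps without k_p: {bad}")
    rows = []
    for _, row in exp.iterrows():
        aid = row["animal_id"]
        if aid not in controls.index:
            raise ValidationError(f"no control means for animal {aid!r}")
        ctrl = controls.loc[aid]
        rec: dict[str, object] = {
            "animal_id": aid,
            "platform_id": row["platform_id"],
            "line_index": row["line_index"],
            "k_p": row["k_p"],
            "regime": assign_regime(float(row["k_p"]), mean_k_g),
        }
        for var in RATIO_VARIABLES:
            if ctrl[var] == 0:
                raise ValidationError(
                    f"zero control mean for {var!r} of animal {aid!r}"
                )
            rec[var] = row[var] / ctrl[var]
        for var in DIFFERENCE_VARIABLES:
            rec[var] = row[var] - ctrl[var]
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OneSampleTestResult:
    """Two-sided one-sample t-test with a normality check and fallback."""

    statistic: float
    pvalue: float
    n: int
    null_mean: float
    shapiro_pvalue: float | None  # None when n < 3 (test undefined)
    normal: bool
    wilcoxon_statistic: float | None = None
    wilcoxon_pvalue: float | None = None


def one_sample_test(
    values, null_mean: float, *, normality_alpha: float = 0.05
) -> OneSampleTestResult:
    """Test whether a sample mean differs from ``null_mean`` (two-sided).

    Runs a one-sample t-test; a Shapiro normality check at
    ``normality_alpha`` decides whether a Wilcoxon signed-rank test is
    reported alongside (samples failing normality keep the t result but
    carry the rank-based statistic for comparison).
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValidationError("one-sample test needs at least 2 values")
    if np.ptp(x) == 0:
        raise DomainError("zero sample variance: test statistic undefined")
    t_stat, t_p = sps.ttest_1samp(x, null_mean)
    shapiro_p: float | None = None
    normal = True
    if x.size >= 3:
        shapiro_p = float(sps.shapiro(x).pvalue)
        normal = shapiro_p >= normality_alpha
    w_stat = w_p = None
    if not normal:
        res = sps.wilcoxon(x - null_mean)
        w_stat, w_p = float(res.statistic), float(res.pvalue)
    return OneSampleTestResult(
        statistic=float(t_stat),
        pvalue=float(t_p),
        n=int(x.size),
        null_mean=float(null_mean),
        shapiro_pvalue=shapiro_p,
        normal=normal,
        wilcoxon_statistic=w_stat,
        wilcoxon_pvalue=w_p,
    )


@dataclass
class RegimeModelResults:
    """Fitted regime model: term table, estimates and the statsmodels result."""

    regime: str
    response: str
    formula: str
    dropped_interaction: bool
    terms: pd.DataFrame  # term, estimate, F, df_num, df_den, p
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    mixedlm_result: object

    def summary(self) -> str:
        head = (
            f"Regime model [{self.regime}] response={self.response}\n"
            f"formula: {self.formula}"
            + (" (interaction dropped)" if self.dropped_interaction else "")
            + "\n"
        )
        return head + self.terms.to_string(index=False)


class RegimeModel:
    """Linear mixed-effects model for one normalized variable in one regime.

    Fixed effects: platform stiffness ``k_p`` as a covariate; in the stiff
    regime additionally platform type and (initially) a stiffness×type
    interaction, which is removed and the model refitted when its p ≥ 0.05.
    A per-animal random intercept absorbs repeated sampling.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        regime: str,
        *,
        stiffness_col: str = "k_p",
        platform_col: str = "platform_id",
        group_col: str = "animal_id",
        interaction_alpha: float = 0.05,
    ):
        if regime not in ("compliant", "stiff"):
            raise ValidationError("regime must be 'compliant' or 'stiff'")
        if "regime" in data.columns:
            data = data[data["regime"] == regime]
        data = data.dropna(subset=[response, stiffness_col]).copy()
        n_groups = data[group_col].nunique()
        if n_groups < 2:
            raise ValidationError(
                "mixed model needs at least 2 animals; random intercept "
                f"inestimable with {n_groups}"
            )
        # fit on a scaled copy of the covariate: platform stiffness spans
        # orders of magnitude and raw N/m values make the REML problem
        # ill-conditioned; pure scaling leaves F, p and the intercept
        # untouched and the slope is rescaled back for reporting
        scale = float(data[stiffness_col].std())
        self._kp_scale = scale if scale > 0 else 1.0
        data = data.copy()
        data["_kp_scaled"] = data[stiffness_col] / self._kp_scale
        self.data = data
        self.response = response
        self.regime = regime
        self.stiffness_col = stiffness_col
        self.platform_col = platform_col
        self.group_col = group_col
        self.interaction_alpha = interaction_alpha
        include_type = regime == "stiff" and data[platform_col].nunique() > 1
        base = f"Q('{response}') ~ _kp_scaled"
        if include_type:
            self.full_formula = base + f" * C(Q('{platform_col}'))"
            self.reduced_formula = base + f" + C(Q('{platform_col}'))"
        else:
            self.full_formula = self.reduced_formula = base

    def _fit_formula(self, formula: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            # near-zero between-animal variance triggers a benign
            # singular-covariance warning on small demo datasets
            warnings.filterwarnings(
                "ignore", message="Random effects covariance is singular"
            )
            model = smf.mixedlm(
                formula, self.data, groups=self.data[self.group_col]
            )
            try:
                return model.fit(reml=True, method=["lbfgs", "bfgs"])
            except np.linalg.LinAlgError:
                return model.fit(reml=True, method="powell")

    @staticmethod
    def _term_table(res) -> pd.DataFrame:
        """Wald F per fixed-effect term with containment denominator df."""
        design = res.model.data.design_info
        k_fe = res.k_fe
        n_obs = res.model.nobs
        n_groups = res.model.n_groups
        df_den = max(int(n_obs - k_fe - (n_groups - 1)), 1)
        rows = []
        names = list(res.model.exog_names)
        for term, sl in design.term_name_slices.items():
            cols = list(range(*sl.indices(k_fe)))
            contrast = np.zeros((len(cols), res.params.shape[0]))
            for i, c in enumerate(cols):
                contrast[i, c] = 1.0
            wt = res.wald_test(contrast, scalar=True)
            df_num = len(cols)
            f_val = float(wt.statistic) / df_num  # chi2 -> F scale
            p = float(sps.f.sf(f_val, df_num, df_den))
            est = float(res.params.iloc[cols[0]]) if df_num == 1 else np.nan
            rows.append(
                {
                    "term": term,
                    "estimate": est,
                    "F": f_val,
                    "df_num": df_num,
                    "df_den": df_den,
                    "p": p,
                    "columns": ", ".join(names[c] for c in cols),
                }
            )
        return pd.DataFrame(rows)

    def fit(self) -> RegimeModelResults:
        res = self._fit_formula(self.full_formula)
        terms = self._term_table(res)
        dropped = False
        formula = self.full_formula
        inter = terms["term"].str.contains(":")
        if inter.any():
            p_inter = float(terms.loc[inter, "p"].iloc[0])
            if p_inter >= self.interaction_alpha:
                res = self._fit_formula(self.reduced_formula)
                terms = self._term_table(res)
                dropped = True
                formula = self.reduced_formula
        k_fe = res.k_fe
        params = res.params.iloc[:k_fe].copy()
        bse = res.bse.iloc[:k_fe].copy()
        ci = res.conf_int().iloc[:k_fe].copy()
        ci.columns = ["ci_low", "ci_high"]
        # undo the internal covariate scaling and restore the column name
        factor = pd.Series(
            [1.0 / self._kp_scale if "_kp_scaled" in n else 1.0 for n in params.index],
            index=params.index,
        )
        params, bse = params * factor, bse * factor
        ci = ci.mul(factor, axis=0)
        rename = {
            n: n.replace("_kp_scaled", f"Q('{self.stiffness_col}')")
            for n in params.index
        }
        params, bse, ci = params.rename(rename), bse.rename(rename), ci.rename(index=rename)
        scaled = terms["columns"].str.contains("_kp_scaled")
        terms.loc[scaled & (terms["df_num"] == 1), "estimate"] /= self._kp_scale
        terms["term"] = terms["term"].str.replace(
            "_kp_scaled", f"Q('{self.stiffness_col}')", regex=False
        )
        return RegimeModelResults(
            regime=self.regime,
            response=self.response,
            formula=formula.replace("_kp_scaled", f"Q('{self.stiffness_col}')"),
            dropped_interaction=dropped,
            terms=terms.drop(columns=["columns"]),
            params=params,
            bse=bse,
            conf_int=ci,
            mixedlm_result=res,
        )


def regime_model_report(
    normalized: pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Fit every (regime, variable) mixed model and stack the term tables."""
    if variables is None:
        variables = NORMALIZED_VARIABLES
    frames = []
    for regime in ("compliant", "stiff"):
        sub = normalized[normalized["regime"] == regime]
        if sub.empty:
            continue
        for var in variables:
            try:
                res = RegimeModel(normalized, var, regime).fit()
            except ValidationError:
                continue
            tab = res.terms.copy()
            tab.insert(0, "variable", var)
            tab.insert(0, "regime", regime)
            tab["dropped_interaction"] = res.dropped_interaction
            frames.append(tab)
    if not frames:
        raise ValidationError("no regime models could be fitted")
    return pd.concat(frames, ignore_index=True)


def one_sample_report(normalized: pd.DataFrame) -> pd.DataFrame:
    """One-sample tests per (platform, line) for every normalized variable.

    Ratio variables are tested against 1.0, elevation against 0.0; groups
    with fewer than two jumps or zero variance are skipped.
    """
    rows = []
    for (pid, line), grp in normalized.groupby(["platform_id", "line_index"]):
        for var in NORMALIZED_VARIABLES:
            null = 0.0 if var in DIFFERENCE_VARIABLES else 1.0
            vals = grp[var].dropna()
            if len(vals) < 2 or np.ptp(vals.to_numpy()) == 0:
                continue
            r = one_sample_test(vals, null)
            rows.append(
                {
                    "platform_id": pid,
                    "line_index": line,
                    "variable": var,
                    "null_mean": null,
                    "n": r.n,
                    "mean": float(vals.mean()),
                    "t": r.statistic,
                    "p": r.pvalue,
                    "shapiro_p": r.shapiro_pvalue,
                    "normal": r.normal,
                    "wilcoxon_p": r.wilcoxon_pvalue,
                }
            )
    return pd.DataFrame(rows)
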