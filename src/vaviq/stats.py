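"""Mixed-effects group comparison and shear-vibration correlation.

The unit of analysis is the slice: 25 per-slice metric means per
vessel, with repeated measures handled by a patient random intercept.
The comparison is statsmodels-shaped: a model object built from the
slice table whose ``fit()`` returns a results object carrying
estimates, their uncertainties, diagnostics and a ``summary()`` table.

Inference conventions
---------------------
* Gaussian linear mixed model fitted by REML (the lmer default; ML
  available via ``reml=False``) — with six patients the ML variance
  components are biased low enough to visibly inflate test size;
  Shapiro-Wilk on the REML residuals; on violation (p < 0.05) the model
  is refitted as a Gamma GLMM with a log link (Laplace approximation,
  ML) and that family is reported.
* Group contrasts are between-patient effects, so Wald statistics are
  referred to a t distribution with between-cluster degrees of freedom
  (n_patients - 1, the cluster-robust convention); with six patients a
  normal reference would be badly anti-conservative.  Slopes of
  within-patient covariates (the shear-index correlations) use the
  normal reference.
* Two-sided alpha = 0.05 for the two-group comparison; Bonferroni
  alpha/3 for the three-group one.
* The conditional correlation coefficient R is the Pearson correlation
  between observations and fitted values including random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
import statsmodels.api as sm

from .gamma_glmm import fit_gamma_glmm

__all__ = [
    "MixedModelResult",
    "GroupComparisonModel",
    "CorrelationResult",
    "IndexCorrelationModel",
    "fit_lmm",
    "correlate_indices",
    "bonferroni",
    "shapiro_wilk",
    "summarize_groups",
    "permutation_test",
]


def bonferroni(alpha: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted significance level, reported at 4 decimals."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return round(alpha / n_comparisons, 4)


def shapiro_wilk(residuals: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic, p-value)."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    w, p = sp_stats.shapiro(residuals)
    return float(w), float(p)


def summarize_groups(slice_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and sample SD per metric, pooled over slices."""
    if slice_table.empty:
        raise ValueError("empty slice table")
    out = (
        slice_table.groupby(["group_label", "metric_name"])["mean_value"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "group_mean", "std": "group_sd", "count": "n_slices"})
    )
    return out


def _pivot(slice_table: pd.DataFrame, response: str) -> pd.DataFrame:
    df = slice_table[slice_table["metric_name"] == response]
    if df.empty:
        raise ValueError(f"no rows for metric {response!r}")
    return df.reset_index(drop=True)


@dataclass
class MixedModelResult:
    """Fitted group-comparison mixed model.

    fixed_effects maps term name -> (estimate, SE); p_values maps
    contrast name -> two-sided p; the family records whether the
    Gaussian LMM passed the residual-normality gate or the Gamma
    log-link refit was used (estimates are then on the log-mean scale).
    """

    response: str
    grouping: str
    model_family: str
    fixed_effects: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    var_patient: float
    var_resid: float
    shapiro_p: float
    conditional_R: float
    df_contrast: int
    alpha_adjusted: float
    n_obs: int
    n_patients: int
    gaussian_fixed_effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.var_patient < 0 or self.var_resid < 0:
            raise ValueError("variance components must be >= 0")
        for p in self.p_values.values():
            if not (0 <= p <= 1):
                raise ValueError("p-values must lie in [0, 1]")

    def summary(self) -> str:
        lines = [
            f"Mixed-effects group comparison: response={self.response!r}, "
            f"design={self.grouping}",
            f"family={self.model_family}  n_obs={self.n_obs}  "
            f"n_patients={self.n_patients}  contrast df={self.df_contrast}",
            f"random-intercept var={self.var_patient:.4g}  "
            f"residual var/dispersion={self.var_resid:.4g}",
            f"residual Shapiro-Wilk p={self.shapiro_p:.3g}   "
            f"conditional R={self.conditional_R:.3f}",
            f"adjusted alpha={self.alpha_adjusted}",
            "",
            f"{'term':<28}{'estimate':>12}{'SE':>12}{'p':>12}",
        ]
        for name, (est, se) in self.fixed_effects.items():
            p = self.p_values.get(name)
            lines.append(
                f"{name:<28}{est:>12.4g}{se:>12.4g}"
                + (f"{p:>12.3g}" if p is not None else f"{'':>12}")
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "grouping": self.grouping,
            "model_family": self.model_family,
            "fixed_effects": {k: list(v) for k, v in self.fixed_effects.items()},
            "p_values": self.p_values,
            "var_patient": self.var_patient,
            "var_resid": self.var_resid,
            "shapiro_p": self.shapiro_p,
            "conditional_R": self.conditional_R,
            "alpha_adjusted": self.alpha_adjusted,
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
        }


class GroupComparisonModel:
    """Random-intercept comparison of a slice metric between groups.

    Parameters
    ----------
    slice_table : long-format table with columns patient_id,
        group_label, metric_name, mean_value.
    response : metric to model (e.g. "amp_um" or "strain_e3").
    grouping : "two_group" (Patency vs Adverse, stenosis and dilatation
        pooled) or "three_group" (all pairs vs Patency, Bonferroni).
    family : "auto" (Gaussian with Gamma fallback on residual
        non-normality), "gaussian", or "gamma".
    """

    def __init__(
        self,
        slice_table: pd.DataFrame,
        response: str,
        grouping: str = "two_group",
        family: str = "auto",
        reml: bool = True,
        alpha: float = 0.05,
    ) -> None:
        if grouping not in ("two_group", "three_group"):
            raise ValueError("grouping must be 'two_group' or 'three_group'")
        if family not in ("auto", "gaussian", "gamma"):
            raise ValueError("family must be auto|gaussian|gamma")
        self.data = _pivot(slice_table, response)
        self.response = response
        self.grouping = grouping
        self.family = family
        self.reml = reml
        self.alpha = alpha
        self._build_design()

    @classmethod
    def from_slice_table(cls, slice_table: pd.DataFrame, response: str, **kw):
        return cls(slice_table, response, **kw)

    def _build_design(self) -> None:
        df = self.data
        self.patients = df["patient_id"].to_numpy()
        n_pat = df["patient_id"].nunique()
        if n_pat < 2:
            raise ValueError("random patient effect unidentifiable with < 2 patients")
        labels = df["group_label"].to_numpy()
        if self.grouping == "two_group":
            grp = np.where(labels == "patency", "patency", "adverse")
            terms = ["adverse_vs_patency"]
            X = np.column_stack([np.ones(len(df)), (grp == "adverse").astype(float)])
        else:
            terms = ["stenosis_vs_patency", "dilatation_vs_patency"]
            X = np.column_stack(
                [
                    np.ones(len(df)),
                    (labels == "stenosis").astype(float),
                    (labels == "dilatation").astype(float),
                ]
            )
        self.exog = X
        self.terms = terms
        self.exog_names = ["intercept"] + terms
        self.n_patients = n_pat
        # between-cluster df, cluster-robust G-1 convention
        self.df_contrast = max(n_pat - 1, 1)
        self.n_comparisons = len(terms)

    def fit(self) -> MixedModelResult:
        y = self.data["mean_value"].to_numpy(dtype=float)
        X = self.exog
        md = sm.MixedLM(y, X, groups=self.patients)
        mdf = _fit_mixedlm(md, reml=self.reml)
        fitted_gauss = _mixedlm_fitted(mdf, X)
        resid = y - fitted_gauss
        shapiro_w, shapiro_p = shapiro_wilk(resid)
        gaussian_fe = {
            name: (float(mdf.fe_params[i]), float(mdf.bse_fe[i]))
            for i, name in enumerate(self.exog_names)
        }

        use_gamma = self.family == "gamma" or (
            self.family == "auto" and shapiro_p < 0.05 and (y > 0).all()
        )
        alpha_adj = (
            bonferroni(self.alpha, self.n_comparisons)
            if self.n_comparisons > 1
            else self.alpha
        )
        if not use_gamma:
            fe = gaussian_fe
            p_values = {
                t: _t_pvalue(fe[t][0] / fe[t][1], self.df_contrast) for t in self.terms
            }
            result = MixedModelResult(
                response=self.response,
                grouping=self.grouping,
                model_family="gaussian",
                fixed_effects=fe,
                p_values=p_values,
                var_patient=float(np.asarray(mdf.cov_re)[0, 0]),
                var_resid=float(mdf.scale),
                shapiro_p=shapiro_p,
                conditional_R=_safe_corr(y, fitted_gauss),
                df_contrast=self.df_contrast,
                alpha_adjusted=alpha_adj,
                n_obs=len(y),
                n_patients=self.n_patients,
                gaussian_fixed_effects=gaussian_fe,
            )
            return result

        gres = fit_gamma_glmm(
            y,
            X,
            self.patients,
            start_sigma_b=max(float(np.sqrt(np.asarray(mdf.cov_re)[0, 0])) / max(abs(y.mean()), 1e-9), 1e-3),
        )
        fe = {
            name: (float(gres.params[i]), float(gres.bse[i]))
            for i, name in enumerate(self.exog_names)
        }
        p_values = {}
        for t in self.terms:
            est, se = fe[t]
            if not np.isfinite(se) or se == 0:
                # fall back to the Gaussian contrast when the Laplace
                # Hessian is ill-conditioned
                est_g, se_g = gaussian_fe[t]
                p_values[t] = _t_pvalue(est_g / se_g, self.df_contrast)
            else:
                p_values[t] = _t_pvalue(est / se, self.df_contrast)
        return MixedModelResult(
            response=self.response,
            grouping=self.grouping,
            model_family="gamma_log",
            fixed_effects=fe,
            p_values=p_values,
            var_patient=float(gres.sigma_b**2),
            var_resid=float(1.0 / gres.shape),
            shapiro_p=shapiro_p,
            conditional_R=_safe_corr(y, gres.fittedvalues),
            df_contrast=self.df_contrast,
            alpha_adjusted=alpha_adj,
            n_obs=len(y),
            n_patients=self.n_patients,
            gaussian_fixed_effects=gaussian_fe,
        )


def _fit_mixedlm(md: sm.MixedLM, reml: bool = False):
    """ML fit with optimizer fallback.

    The default gradient optimizer occasionally diverges on
    boundary-variance problems (infinite log-likelihood, absurd SEs);
    derivative-free optimizers are tried as well and the best finite,
    sane fit wins.
    """
    import warnings as _w

    fallback = None
    for method in (None, "powell", "nm"):
        try:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                mdf = md.fit(reml=reml) if method is None else md.fit(
                    reml=reml, method=method
                )
        except (np.linalg.LinAlgError, ValueError):
            continue
        bse = np.asarray(mdf.bse_fe)
        if np.isfinite(float(mdf.llf)) and np.all(np.isfinite(bse)) and np.all(bse > 0):
            return mdf
        fallback = fallback or mdf
    if fallback is None:
        raise RuntimeError("mixed-model fit failed with every optimizer")
    return fallback


def _mixedlm_fitted(mdf, X: np.ndarray) -> np.ndarray:
    """Conditional (fixed + random) fitted values; falls back to the
    fixed-effect fit when the random-intercept variance collapses to
    zero (singular covariance)."""
    try:
        return np.asarray(mdf.fittedvalues)
    except (ValueError, np.linalg.LinAlgError):
        return X @ np.asarray(mdf.fe_params)


def _t_pvalue(t_stat: float, df: int) -> float:
    return float(2.0 * sp_stats.t.sf(abs(t_stat), df))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_lmm(
    slice_table: pd.DataFrame,
    response: str,
    grouping: str = "two_group",
    **kwargs,
) -> MixedModelResult:
    """Convenience wrapper: build and fit a :class:`GroupComparisonModel`."""
    return GroupComparisonModel(slice_table, response, grouping, **kwargs).fit()


# ----------------------------------------------------------- correlations


@dataclass
class CorrelationResult:
    index_name: str
    vib_name: str
    slope: float
    slope_se: float
    p_value: float
    conditional_R: float
    log10_transformed: bool
    n_obs: int

    def to_dict(self) -> dict:
        return vars(self).copy()


class IndexCorrelationModel:
    """Mixed-model correlation between one shear index and one vibration
    metric, with a patient random intercept.

    The slope is a within-patient covariate effect, tested against the
    normal reference; R is the correlation of observations with the
    conditional (fixed + random) fit.
    """

    def __init__(
        self,
        index_values: np.ndarray,
        vib_values: np.ndarray,
        patient_ids: np.ndarray,
        index_name: str = "index",
        vib_name: str = "vibration",
        log10_vib: bool = False,
    ) -> None:
        self.x = np.asarray(index_values, dtype=float)
        self.y = np.asarray(vib_values, dtype=float)
        self.patients = np.asarray(patient_ids)
        if not (len(self.x) == len(self.y) == len(self.patients)):
            raise ValueError("index, vibration and patient arrays must align")
        if np.unique(self.patients).size < 2:
            raise ValueError("random patient effect unidentifiable with < 2 patients")
        self.index_name = index_name
        self.vib_name = vib_name
        self.log10_vib = log10_vib

    def fit(self) -> CorrelationResult:
        y = self.y
        if self.log10_vib:
            if (y <= 0).any():
                raise ValueError("log10 transform needs positive vibration values")
            y = np.log10(y)
        X = np.column_stack([np.ones_like(self.x), self.x])
        md = sm.MixedLM(y, X, groups=self.patients)
        mdf = _fit_mixedlm(md, reml=False)
        slope = float(mdf.fe_params[1])
        se = float(mdf.bse_fe[1])
        z = slope / se if se > 0 else np.inf
        p = float(2.0 * sp_stats.norm.sf(abs(z)))
        fitted = _mixedlm_fitted(mdf, X)
        return CorrelationResult(
            index_name=self.index_name,
            vib_name=self.vib_name,
            slope=slope,
            slope_se=se,
            p_value=min(p, 1.0),
            conditional_R=_safe_corr(y, fitted),
            log10_transformed=self.log10_vib,
            n_obs=len(y),
        )


def correlate_indices(
    slice_table_wss: pd.DataFrame,
    slice_table_vib: pd.DataFrame,
    log_transform: bool = False,
    index_names: tuple[str, ...] = ("tawss", "osi", "spi"),
    vib_names: tuple[str, ...] = ("amp_um", "strain_e3"),
) -> pd.DataFrame:
    """Mixed-model correlation for every (shear index, vibration metric)
    pair, matching slices on (patient_id, slice_index)."""
    rows = []
    for idx_name in index_names:
        wss = _pivot(slice_table_wss, idx_name)[
            ["patient_id", "slice_index", "mean_value"]
        ].rename(columns={"mean_value": "x"})
        for vib_name in vib_names:
            vib = _pivot(slice_table_vib, vib_name)[
                ["patient_id", "slice_index", "mean_value"]
            ].rename(columns={"mean_value": "y"})
            merged = wss.merge(vib, on=["patient_id", "slice_index"], how="inner")
            if merged.empty:
                raise ValueError(
                    f"no matched slices for ({idx_name}, {vib_name})"
                )
            res = IndexCorrelationModel(
                merged["x"].to_numpy(),
                merged["y"].to_numpy(),
                merged["patient_id"].to_numpy(),
                index_name=idx_name,
                vib_name=vib_name,
                log10_vib=log_transform,
            ).fit()
            rows.append(res.to_dict())
    return pd.DataFrame(rows)


# ------------------------------------------------------- permutation check


def permutation_test(
    slice_table: pd.DataFrame,
    response: str,
    seed: int = 0,
    max_permutations: int = 20000,
) -> float:
    """Distribution-free patient-level check of the Patency-vs-Adverse
    difference: permute group labels across patients, statistic is the
    difference of group means of patient means.  Exact enumeration when
    feasible.  With 6 patients (2 vs 4) the smallest attainable p is
    1/15."""
    from itertools import combinations

    df = _pivot(slice_table, response)
    pm = df.groupby("patient_id").agg(
        value=("mean_value", "mean"), group=("group_label", "first")
    )
    labels = np.where(pm["group"].to_numpy() == "patency", 0, 1)
    vals = pm["value"].to_numpy()
    n = len(vals)
    k = int(labels.sum())

    def stat(mask):
        return abs(vals[mask].mean() - vals[~mask].mean())

    obs = stat(labels.astype(bool))
    combos = list(combinations(range(n), k))
    if len(combos) > max_permutations:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(combos), size=max_permutations, replace=False)
        combos = [combos[i] for i in sel]
    count = 0
    for c in combos:
        mask = np.zeros(n, dtype=bool)
        mask[list(c)] = True
        if stat(mask) >= obs - 1e-12:
            count += 1
    return count / len(combos)
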