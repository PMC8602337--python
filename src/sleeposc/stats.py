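"""Aggregation and linear mixed-effects inference for night-level metrics.

Event characteristics, densities, band powers and global sleep statistics
are first averaged within (subject, condition, stage, melatonin) cells;
the cell means are then modelled with a random-intercept linear mixed
model

    y = Condition + Stage + Condition:Stage + Melatonin + (1 | subject)

(slow-wave and global-sleep metrics carry no Stage term).  Models are
fitted by REML through statsmodels' MixedLM.  On top of the fit this
module computes:

* type-III F-tests per fixed term (sum-to-zero factor coding, Wald F on
  the term's coefficients), with Satterthwaite denominator degrees of
  freedom;
* estimated marginal means (EMMs) per condition, averaging over the other
  factors with equal weights;
* all pairwise condition contrasts with two-sided Tukey HSD adjustment
  and Tukey-based 95% confidence intervals;
* Shapiro–Wilk normality check on the conditional residuals;
* AIC (models refitted by maximum likelihood for comparability).

Satterthwaite degrees of freedom are obtained from the closed-form REML
log-likelihood of the random-intercept model: for a contrast c,
df = 2 g² / (∇g' A ∇g) with g(θ) = c'(X'V(θ)⁻¹X)⁻¹c and A the inverse
observed information of the REML criterion in θ = (σ²_residual,
σ²_subject), derivatives taken by central finite differences.  Multi-df
terms combine per-eigencontrast dfs as in the standard mixed-model
F-test approximation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.stats import studentized_range

from .errors import ComparabilityError, EstimationError, IntegrityError

CONDITION_LEVELS = ("PRE", "IN", "POST")
STAGE_LEVELS = ("N2", "N3")
MELATONIN_LEVELS = ("placebo", "active")

CONTRAST_PAIRS = (("IN", "POST"), ("IN", "PRE"), ("POST", "PRE"))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate(df: pd.DataFrame, stage_key: bool = True) -> pd.DataFrame:
    """Average metric values within (subject, condition[, stage], melatonin).

    ``df`` must be tidy with columns ``subject_id, session_id, condition,
    melatonin, metric, value`` and, when ``stage_key`` is true, ``stage``.
    Sessions and channels are averaged over; empty cells are simply absent.
    Raises :class:`IntegrityError` if one session carries conflicting
    condition/melatonin metadata.
    """
    required = {"subject_id", "session_id", "condition", "melatonin",
                "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise IntegrityError(f"missing columns: {sorted(missing)}")
    meta = df.groupby(["subject_id", "session_id"])[
        ["condition", "melatonin"]].nunique()
    bad = meta[(meta > 1).any(axis=1)]
    if len(bad):
        raise IntegrityError(
            f"conflicting metadata for sessions: {list(bad.index)}")
    keys = ["subject_id", "condition", "melatonin", "metric"]
    if stage_key:
        keys.insert(2, "stage")
    out = (df.dropna(subset=["value"])
             .groupby(keys, as_index=False)["value"].mean())
    return out


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one mixed model."""

    response: str
    include_stage: bool = True
    include_interaction: bool = True
    include_melatonin: bool = True
    reml: bool = True


def _sum_code(values: np.ndarray, levels: tuple[str, ...]) -> np.ndarray:
    """Sum-to-zero (deviation) coding: one column per non-reference level."""
    k = len(levels)
    out = np.zeros((values.size, k - 1))
    for j, lev in enumerate(levels[:-1]):
        out[:, j] = np.where(values == lev, 1.0,
                             np.where(values == levels[-1], -1.0, 0.0))
    return out


def _build_design(table: pd.DataFrame, spec: ModelSpec
                  ) -> tuple[np.ndarray, dict[str, list[int]], list[str]]:
    """Design matrix with sum coding; returns (X, term -> column idx, names)."""
    n = len(table)
    cols = [np.ones((n, 1))]
    names = ["Intercept"]
    terms: dict[str, list[int]] = {}

    cond = _sum_code(table["condition"].to_numpy(), CONDITION_LEVELS)
    terms["Condition"] = list(range(len(names), len(names) + cond.shape[1]))
    cols.append(cond)
    names += [f"Condition[{l}]" for l in CONDITION_LEVELS[:-1]]

    if spec.include_stage:
        stage = _sum_code(table["stage"].to_numpy(), STAGE_LEVELS)
        terms["Stage"] = list(range(len(names), len(names) + stage.shape[1]))
        cols.append(stage)
        names += [f"Stage[{l}]" for l in STAGE_LEVELS[:-1]]
        if spec.include_interaction:
            inter = np.concatenate(
                [cond[:, [i]] * stage for i in range(cond.shape[1])], axis=1)
            terms["Condition:Stage"] = list(
                range(len(names), len(names) + inter.shape[1]))
            cols.append(inter)
            names += [f"Condition[{c}]:Stage[{s}]"
                      for c in CONDITION_LEVELS[:-1] for s in STAGE_LEVELS[:-1]]

    if spec.include_melatonin and table["melatonin"].nunique() > 1:
        mel = _sum_code(table["melatonin"].to_numpy(), MELATONIN_LEVELS)
        terms["Melatonin"] = list(range(len(names), len(names) + mel.shape[1]))
        cols.append(mel)
        names += ["Melatonin[placebo]"]

    return np.concatenate(cols, axis=1), terms, names


def _grid_row(condition: str, stage: str | None, melatonin: str | None,
              spec: ModelSpec, terms: dict[str, list[int]], p: int) -> np.ndarray:
    """Design row for one factorial grid cell (for EMM construction)."""
    row = np.zeros(p)
    row[0] = 1.0

    def code(value: str, levels: tuple[str, ...]) -> np.ndarray:
        v = np.zeros(len(levels) - 1)
        if value == levels[-1]:
            v[:] = -1.0
        else:
            v[levels.index(value)] = 1.0
        return v

    ccode = code(condition, CONDITION_LEVELS)
    row[terms["Condition"]] = ccode
    if spec.include_stage and stage is not None:
        scode = code(stage, STAGE_LEVELS)
        row[terms["Stage"]] = scode
        if spec.include_interaction and "Condition:Stage" in terms:
            row[terms["Condition:Stage"]] = np.outer(ccode, scode).ravel()
    if "Melatonin" in terms and melatonin is not None:
        row[terms["Melatonin"]] = code(melatonin, MELATONIN_LEVELS)
    return row


# ---------------------------------------------------------------------------
# REML machinery for Satterthwaite degrees of freedom
# ---------------------------------------------------------------------------

class _RandomInterceptREML:
    """Closed-form REML criterion for a random-intercept LMM."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = y
        self.X = X
        order = np.argsort(groups, kind="stable")
        self.groups = [np.flatnonzero(groups == g)
                       for g in pd.unique(groups[order])]

    def _whitened(self, s2e: float, s2b: float):
        """Accumulate X'V⁻¹X, X'V⁻¹y, y'V⁻¹y and log|V| by group."""
        p = self.X.shape[1]
        M = np.zeros((p, p))
        v = np.zeros(p)
        yy = 0.0
        logdet = 0.0
        for idx in self.groups:
            Xg = self.X[idx]
            yg = self.y[idx]
            ng = len(idx)
            denom = s2e + ng * s2b
            logdet += (ng - 1) * np.log(s2e) + np.log(denom)
            sx = Xg.sum(axis=0)
            sy = yg.sum()
            w = s2b / denom
            M += (Xg.T @ Xg - w * np.outer(sx, sx)) / s2e
            v += (Xg.T @ yg - w * sx * sy) / s2e
            yy += (yg @ yg - w * sy * sy) / s2e
        return M, v, yy, logdet

    def loglike(self, s2e: float, s2b: float) -> float:
        if s2e <= 1e-300 or s2b < 0:
            return -np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            M, v, yy, logdet = self._whitened(s2e, s2b)
        if not np.isfinite(logdet):
            return -np.inf
        sign, logdet_m = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(M, v)
        quad = yy - v @ beta
        return -0.5 * (logdet + logdet_m + quad)

    def beta_cov(self, s2e: float, s2b: float):
        M, v, _, _ = self._whitened(s2e, s2b)
        Minv = np.linalg.inv(M)
        return Minv @ v, Minv

    def prepare_satterthwaite(self, s2e: float, s2b: float) -> None:
        """Precompute, once per fit, everything shared across contrasts.

        Stores the fixed-effect covariance, its derivatives with respect
        to the two variance parameters (central differences), and the
        inverse observed REML information of those parameters.
        """
        theta = np.array([s2e, max(s2b, 0.0)])
        n, p = self.X.shape
        self._fallback_df = float(max(n - p, 1))
        self._cov0 = self.beta_cov(s2e, max(s2b, 0.0))[1]
        self._sat_ready = s2b > 1e-10 * s2e
        if not self._sat_ready:
            return
        h = np.maximum(1e-4 * theta, 1e-10)
        self._dcov = []
        for i in range(2):
            e = np.zeros(2)
            e[i] = h[i]
            cp = self.beta_cov(*(theta + e))[1]
            cm = self.beta_cov(*(theta - e))[1]
            self._dcov.append((cp - cm) / (2 * h[i]))
        H = np.zeros((2, 2))
        f0 = self.loglike(*theta)
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                with np.errstate(invalid="ignore"):
                    if i == j:
                        H[i, i] = (self.loglike(*(theta + ei)) - 2 * f0
                                   + self.loglike(*(theta - ei))) / h[i] ** 2
                    else:
                        H[i, j] = H[j, i] = (
                            self.loglike(*(theta + ei + ej))
                            - self.loglike(*(theta + ei - ej))
                            - self.loglike(*(theta - ei + ej))
                            + self.loglike(*(theta - ei - ej))) / (4 * h[i] * h[j])
        if not np.isfinite(H).all():
            self._sat_ready = False
            return
        try:
            self._information_inv = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            self._sat_ready = False

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Satterthwaite df for the scalar contrast c'β.

        ``prepare_satterthwaite`` must have been called for this fit.
        """
        if not self._sat_ready:
            return self._fallback_df
        g = float(c @ self._cov0 @ c)
        grad = np.array([float(c @ d @ c) for d in self._dcov])
        var_g = float(grad @ self._information_inv @ grad)
        if var_g <= 0 or not np.isfinite(var_g) or g <= 0:
            return self._fallback_df
        df = 2.0 * g ** 2 / var_g
        if not np.isfinite(df) or df <= 0:
            return self._fallback_df
        return min(df, 1e6)


def _combine_f_df(dfs: np.ndarray, q: int, fallback: float) -> float:
    """Combine per-eigencontrast Satterthwaite dfs into one denominator df."""
    dfs = dfs[np.isfinite(dfs) & (dfs > 2.0)]
    if dfs.size == 0:
        return fallback
    E = float(np.sum(dfs / (dfs - 2.0)))
    if E <= q:
        return fallback
    return 2.0 * E / (E - q)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    spec: ModelSpec
    n_obs: int
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2_residual: float
    sigma2_subject: float
    singular: bool
    anova: pd.DataFrame          # term, F, df_num, df_den, p
    emms: pd.DataFrame           # level, emm, se, df
    contrasts: pd.DataFrame      # contrast, estimate, se, df, t, p, CI
    shapiro_stat: float
    shapiro_p: float
    aic: float
    converged: bool = True


def fit_lmm(table: pd.DataFrame, spec: ModelSpec,
            tukey: bool = True) -> ModelResult:
    """Fit the random-intercept LMM for one metric and derive inference.

    ``table`` is one metric's slice of the aggregated summary (columns
    ``subject_id, condition[, stage], melatonin, value``).  ``tukey``
    controls whether the familywise-adjusted p-values and Tukey-based
    confidence intervals are computed (they dominate the runtime of large
    simulation studies and can be skipped there).
    """
    import statsmodels.api as sm

    table = table.reset_index(drop=True)
    if table["subject_id"].nunique() < 2:
        raise EstimationError("need at least two subjects")
    y = table["value"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise EstimationError("response does not vary")
    X, terms, names = _build_design(table, spec)
    groups = table["subject_id"].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        fit = None
        last_exc: Exception | None = None
        for method in ("lbfgs", "powell", "nm", "bfgs"):
            try:
                cand = model.fit(reml=spec.reml, method=method)
            except Exception as exc:  # singular hessian etc.; try next optimizer
                last_exc = exc
                continue
            # some optimizers report convergence with a degenerate likelihood
            if np.isfinite(cand.llf) and np.isfinite(cand.scale) and cand.scale > 0:
                fit = cand
                break
        if fit is None:
            raise EstimationError(
                f"mixed model failed to converge: {last_exc}") from last_exc

    s2e = float(fit.scale)
    s2b = float(np.asarray(fit.cov_re)[0, 0])
    singular = s2b <= 1e-8 * max(s2e, 1e-12)

    reml = _RandomInterceptREML(y, X, groups)
    reml.prepare_satterthwaite(s2e, s2b)
    beta, cov = reml.beta_cov(s2e, max(s2b, 0.0))
    n, p = X.shape
    resid_df = float(max(n - p, 1))

    # --- type-III F tests -------------------------------------------------
    anova_rows = []
    for term, idx in terms.items():
        L = np.zeros((len(idx), p))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        q = len(idx)
        Lb = L @ beta
        LCL = L @ cov @ L.T
        try:
            F = float(Lb @ np.linalg.solve(LCL, Lb)) / q
        except np.linalg.LinAlgError:
            continue
        eigvals, eigvecs = np.linalg.eigh(LCL)
        PtL = eigvecs.T @ L
        dfs = np.array([reml.satterthwaite_df(PtL[i]) for i in range(q)])
        df_den = _combine_f_df(dfs, q, resid_df)
        pval = float(sp_stats.f.sf(F, q, df_den))
        anova_rows.append({"term": term, "F": F, "df_num": q,
                           "df_den": df_den, "p": pval})
    anova = pd.DataFrame(anova_rows)

    # --- EMMs over the condition factor -----------------------------------
    stage_levels = STAGE_LEVELS if spec.include_stage else (None,)
    mel_levels = MELATONIN_LEVELS if "Melatonin" in terms else (None,)
    emm_rows = []
    L_by_level: dict[str, np.ndarray] = {}
    for clev in CONDITION_LEVELS:
        rows = [_grid_row(clev, s, m, spec, terms, p)
                for s, m in itertools.product(stage_levels, mel_levels)]
        Lrow = np.mean(rows, axis=0)
        L_by_level[clev] = Lrow
        est = float(Lrow @ beta)
        se = float(np.sqrt(Lrow @ cov @ Lrow))
        df = reml.satterthwaite_df(Lrow)
        emm_rows.append({"level": clev, "emm": est, "se": se, "df": df})
    emms = pd.DataFrame(emm_rows)

    # --- pairwise contrasts (Tukey HSD adjustment optional) ----------------
    # the adjusted p and Tukey-based CI match multiple-comparison reporting
    # conventions; the unadjusted 95% CI is the per-contrast interval used
    # for coverage checks
    k = len(CONDITION_LEVELS)
    contrast_rows = []
    for a, b in CONTRAST_PAIRS:
        Lc = L_by_level[a] - L_by_level[b]
        est = float(Lc @ beta)
        se = float(np.sqrt(Lc @ cov @ Lc))
        df = reml.satterthwaite_df(Lc)
        t = est / se if se > 0 else np.inf
        p_unadj = 2.0 * float(sp_stats.t.sf(abs(t), df))
        t_crit = float(sp_stats.t.ppf(0.975, df))
        row = {
            "contrast": f"{a}-{b}", "estimate": est, "se": se, "df": df,
            "t": t, "p": p_unadj, "p_unadjusted": p_unadj,
            "ci_lower": est - t_crit * se, "ci_upper": est + t_crit * se,
            "ci_lower_unadjusted": est - t_crit * se,
            "ci_upper_unadjusted": est + t_crit * se,
        }
        if tukey:
            p_tukey = float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            crit = float(studentized_range.ppf(0.95, k, df)) / np.sqrt(2.0)
            row.update({"p": p_tukey, "ci_lower": est - crit * se,
                        "ci_upper": est + crit * se})
        contrast_rows.append(row)
    contrasts = pd.DataFrame(contrast_rows)

    # --- conditional residuals & diagnostics --------------------------------
    r_marg = y - X @ beta
    resid = r_marg.copy()
    for idx in reml.groups:
        ng = len(idx)
        shrink = ng * s2b / (s2e + ng * s2b) if s2b > 0 else 0.0
        resid[idx] = r_marg[idx] - shrink * np.mean(r_marg[idx])
    if np.ptp(resid) > 0 and len(resid) >= 3:
        sh_stat, sh_p = sp_stats.shapiro(resid)
    else:
        sh_stat, sh_p = np.nan, np.nan

    # AIC from an ML refit (REML AICs are not comparable across fixed effects)
    aic = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "nm"):
            try:
                ml_fit = sm.MixedLM(y, X, groups=groups).fit(
                    reml=False, method=method)
            except Exception:
                continue
            if np.isfinite(ml_fit.llf):
                aic = float(ml_fit.aic)
                break

    return ModelResult(
        spec=spec, n_obs=n,
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        sigma2_residual=s2e, sigma2_subject=s2b, singular=singular,
        anova=anova, emms=emms, contrasts=contrasts,
        shapiro_stat=float(sh_stat), shapiro_p=float(sh_p), aic=aic)


@dataclass
class AICComparison:
    aic_full: float
    aic_reduced: float
    preferred: str            # "full" or "reduced"

    @property
    def delta(self) -> float:
        return self.aic_full - self.aic_reduced


def compare_models(table: pd.DataFrame, full_spec: ModelSpec,
                   reduced_spec: ModelSpec) -> AICComparison:
    """AIC comparison of two fixed-effect structures on the same rows.

    Both models are refitted by maximum likelihood.  Raises
    :class:`ComparabilityError` when the responses differ.
    """
    if full_spec.response != reduced_spec.response:
        raise ComparabilityError("models must share one response")
    full = fit_lmm(table, ModelSpec(**{**full_spec.__dict__, "reml": False}),
                   tukey=False)
    red = fit_lmm(table, ModelSpec(**{**reduced_spec.__dict__, "reml": False}),
                  tukey=False)
    if full.n_obs != red.n_obs:
        raise ComparabilityError("model fits use different row sets")
    preferred = "full" if full.aic <= red.aic else "reduced"
    return AICComparison(aic_full=full.aic, aic_reduced=red.aic,
                         preferred=preferred)


def report_table(results: dict[str, ModelResult],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Formatted contrast table: one row per pairwise condition contrast.

    Columns: metric, contrast, effect_size, se, df, t, p, ci_lower,
    ci_upper, significant.
    """
    rows = []
    for metric, res in results.items():
        for _, c in res.contrasts.iterrows():
            rows.append({
                "metric": metric, "contrast": c["contrast"],
                "effect_size": c["estimate"], "se": c["se"], "df": c["df"],
                "t": c["t"], "p": c["p"], "ci_lower": c["ci_lower"],
                "ci_upper": c["ci_upper"], "significant": bool(c["p"] < alpha),
            })
    cols = ["metric", "contrast", "effect_size", "se", "df", "t", "p",
            "ci_lower", "ci_upper", "significant"]
    return pd.DataFrame(rows, columns=cols)
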