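"""Random-intercept mixed models with per-fish residual variances.

The activity measures are modelled as

    y_ij = alpha + beta_FL * FL_j + beta_X * X_j + a_j + e_ij

with observations ``i`` nested in fish ``j``, a Gaussian random intercept
``a_j ~ N(0, sigma_a^2)`` and heteroscedastic residuals
``e_ij ~ N(0, sigma_j^2)`` whose variance differs among fish.  Because the
residual variance is fish-specific, repeatability is also fish-specific:

    ICC_j = sigma_a^2 / (sigma_a^2 + sigma_j^2).

Estimation maximises the Gaussian (restricted) log-likelihood over the
variance parameters on the log scale, with the fixed effects profiled out
by generalised least squares; the marginal covariance of each fish's
response vector, ``V_j = sigma_j^2 I + sigma_a^2 J``, admits closed-form
inverse and determinant (Woodbury), so each likelihood evaluation is O(N).

Model selection compares an intercept-only model (M0), a fork-length model
(M1) and models adding one phenotype covariate at a time (M1a..) by AIC and
likelihood-ratio tests under ML; the selected model is refitted by REML for
reported estimates.  Interfaces follow statsmodels: a model object whose
``fit`` returns a results object with a ``summary``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start converges; carries the trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


def transform_response(y, measure: str):
    """Apply the measure-specific response transform.

    Instantaneous speed is ``log(y + 0.1)``-transformed to meet the
    normality assumption; other measures pass through unchanged.
    """
    y = np.asarray(y, dtype=float)
    if measure.lower() in ("u_inst", "uinst"):
        if np.any(y <= -0.1):
            raise ValueError("u_inst transform requires y > -0.1")
        return np.log(y + 0.1)
    return y


def inverse_transform_response(y, measure: str):
    y = np.asarray(y, dtype=float)
    if measure.lower() in ("u_inst", "uinst"):
        return np.exp(y) - 0.1
    return y


class HetVarMixedLM:
    """Random-intercept LMM with a separate residual variance per group.

    Parameters
    ----------
    endog : ndarray (n,)
        Response vector.
    exog : ndarray (n, p)
        Fixed-effects design matrix (include the intercept column).
    groups : ndarray (n,)
        Group (fish) label per observation.
    exog_names : list of str, optional
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != len(self.endog):
            self.exog = self.exog.T
        self.groups = np.asarray(groups)
        self.group_labels, self.group_idx = np.unique(self.groups, return_inverse=True)
        self.n_groups = len(self.group_labels)
        self.nobs = len(self.endog)
        self.k_fe = self.exog.shape[1]
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i}" for i in range(self.k_fe)
        ]
        counts = np.bincount(self.group_idx)
        if self.n_groups < 2 or np.sum(counts >= 2) < 2:
            raise ValueError(
                "need >=2 groups with >=2 observations for variance identifiability"
            )
        singles = self.group_labels[counts == 1]
        if len(singles):
            logger.warning(
                "groups with a single observation (their residual SD is weakly "
                "identified): %s", list(singles),
            )

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str, covariates=(), group: str = "fish_id"
    ) -> "HetVarMixedLM":
        """Build the model from a tidy per-observation table."""
        df = data.dropna(subset=[response, group, *covariates])
        X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates]
        )
        return cls(
            endog=df[response].to_numpy(dtype=float),
            exog=X,
            groups=df[group].to_numpy(),
            exog_names=["intercept", *covariates],
        )

    # ------------------------------------------------------------ likelihood

    def _profile_loglike(self, log_sigma_a, log_sigma_j, reml: bool):
        """Profiled (restricted) log-likelihood at given variance parameters.

        Returns (loglik, beta_hat, cov_beta).
        """
        sa2 = np.exp(2.0 * log_sigma_a)
        sj2 = np.exp(2.0 * np.asarray(log_sigma_j, dtype=float))
        y, X, idx = self.endog, self.exog, self.group_idx
        se2 = sj2[idx]  # residual variance per observation

        # Woodbury pieces, aggregated per group
        w = 1.0 / se2
        sw = np.bincount(idx, weights=w, minlength=self.n_groups)
        lam = sa2 / (1.0 + sa2 * sw)  # scalar correction per group

        def vinv_dot(v):
            """V^{-1} v for a stack of per-observation vectors."""
            wv = w * v
            gsum = np.bincount(idx, weights=wv, minlength=self.n_groups)
            return wv - w * (lam * gsum)[idx]

        XtVi = np.column_stack([vinv_dot(X[:, k]) for k in range(self.k_fe)])
        XtViX = X.T @ XtVi
        XtViy = XtVi.T @ y
        try:
            cov_unscaled = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        beta = cov_unscaled @ XtViy
        r = y - X @ beta
        quad = float(r @ vinv_dot(r))
        counts = np.bincount(idx, minlength=self.n_groups)
        logdet = float(
            np.sum((counts - 1) * np.log(sj2) + np.log(sj2 + counts * sa2))
        )
        ll = -0.5 * (self.nobs * _LOG2PI + logdet + quad)
        if reml:
            sign, ld = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return -np.inf, None, None
            ll += 0.5 * self.k_fe * _LOG2PI - 0.5 * ld
        return ll, beta, cov_unscaled

    def loglike(self, sigma_a, sigma_j, reml=False) -> float:
        """Profiled log-likelihood at given variance parameters (natural scale)."""
        ll, _, _ = self._profile_loglike(
            np.log(sigma_a), np.log(np.asarray(sigma_j, dtype=float)), reml
        )
        return ll

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        method: str = "ml",
        *,
        equal_variances: bool = False,
        n_starts: int = 3,
        seed: int = 0,
        maxiter: int = 2000,
    ) -> "HetVarMixedLMResults":
        """Maximise the (restricted) likelihood over log-variance parameters.

        ``equal_variances=True`` constrains all per-fish residual SDs to a
        common value, reducing the model to a standard random-intercept LMM.
        Multi-start quasi-Newton (L-BFGS-B) on the log scale guards against
        flat likelihoods at small numbers of fish.
        """
        reml = method.lower() == "reml"
        rng = np.random.default_rng(seed)
        n_var = 2 if equal_variances else 1 + self.n_groups

        # moment-based starting values
        resid = self.endog - self.exog @ np.linalg.lstsq(
            self.exog, self.endog, rcond=None
        )[0]
        total_sd = max(np.std(resid), 1e-6)
        group_means = np.bincount(self.group_idx, weights=resid) / np.bincount(
            self.group_idx
        )
        between_sd = max(np.std(group_means), 1e-3 * total_sd)
        start0 = np.log(np.r_[between_sd, np.full(n_var - 1, total_sd)])

        def objective(theta):
            ls_a = theta[0]
            ls_j = (
                np.full(self.n_groups, theta[1]) if equal_variances else theta[1:]
            )
            ll, _, _ = self._profile_loglike(ls_a, ls_j, reml)
            return -ll if np.isfinite(ll) else 1e12

        best, trace = None, []
        for s in range(n_starts):
            theta0 = start0 if s == 0 else start0 + rng.normal(0, 0.5, size=n_var)
            # relative floor on every SD: fish observed a handful of times can
            # otherwise drive their sigma_j to 0, making the heteroscedastic
            # likelihood unbounded and the GLS weights singular
            res = optimize.minimize(
                objective,
                theta0,
                method="L-BFGS-B",
                bounds=[(np.log(1e-3 * total_sd), np.log(1e3 * total_sd))] * n_var,
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
            )
            trace.append(res)
            if res.success or np.isfinite(res.fun):
                if best is None or res.fun < best.fun:
                    best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("variance optimisation failed", trace=trace)

        theta = best.x
        ls_a = theta[0]
        ls_j = np.full(self.n_groups, theta[1]) if equal_variances else theta[1:]
        ll, beta, cov_beta = self._profile_loglike(ls_a, ls_j, reml)
        sigma_a = float(np.exp(ls_a))
        sigma_j = np.exp(ls_j)
        n_params = self.k_fe + (2 if equal_variances else 1 + self.n_groups)
        aic = -2.0 * ll + 2.0 * n_params
        return HetVarMixedLMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(
                cov_beta, index=self.exog_names, columns=self.exog_names
            ),
            sigma_a=sigma_a,
            sigma_j=pd.Series(sigma_j, index=self.group_labels),
            llf=float(ll),
            aic=float(aic),
            method="reml" if reml else "ml",
            n_params=n_params,
            converged=bool(any(r.success for r in trace)),
            equal_variances=equal_variances,
        )


@dataclass
class HetVarMixedLMResults:
    """Estimates, uncertainties and diagnostics of a fitted model."""

    model: HetVarMixedLM
    params: pd.Series
    cov_params: pd.DataFrame
    sigma_a: float
    sigma_j: pd.Series
    llf: float
    aic: float
    method: str
    n_params: int
    converged: bool
    equal_variances: bool = False

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    @property
    def icc(self) -> pd.Series:
        """Per-fish intraclass correlation sigma_a^2/(sigma_a^2+sigma_j^2)."""
        sa2 = self.sigma_a**2
        return sa2 / (sa2 + self.sigma_j**2)

    def icc_summary(self) -> dict:
        icc = self.icc
        return {
            "median": float(icc.median()),
            "min": float(icc.min()),
            "max": float(icc.max()),
        }

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Random-intercept LMM with per-fish residual variances ({self.method.upper()})",
            "=" * 66,
            f"groups: {self.model.n_groups}   obs: {self.model.nobs}   "
            f"loglik: {self.llf:.3f}   AIC: {self.aic:.2f}",
            "",
            f"{'term':<12}{'estimate':>12}{'SE':>12}{'95% CI':>26}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<12}{self.params[name]:>12.4g}{self.bse[name]:>12.4g}"
                f"      [{ci.loc[name, 'lower']:.4g}, {ci.loc[name, 'upper']:.4g}]"
            )
        s = self.icc_summary()
        lines += [
            "",
            f"sigma_a (between-fish SD): {self.sigma_a:.4g}",
            f"sigma_j (residual SD): median {self.sigma_j.median():.4g} "
            f"(range {self.sigma_j.min():.4g} - {self.sigma_j.max():.4g})",
            f"ICC per fish: median {s['median']:.3g} "
            f"(range {s['min']:.3g} - {s['max']:.3g})",
        ]
        return "\n".join(lines)


def lrt(full: HetVarMixedLMResults, reduced: HetVarMixedLMResults) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (statistic, df, p-value)."""
    if full.method != "ml" or reduced.method != "ml":
        logger.warning("LRT on non-ML fits")
    stat = max(2.0 * (full.llf - reduced.llf), 0.0)
    df = full.n_params - reduced.n_params
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return stat, df, p


@dataclass
class SelectionResult:
    """AIC/LRT model-selection grid for one activity measure."""

    measure: str
    table: pd.DataFrame
    best_name: str
    best_ml: HetVarMixedLMResults
    best_reml: HetVarMixedLMResults


def model_select(
    data: pd.DataFrame,
    response: str,
    measure: str,
    candidates: dict[str, str] | None = None,
    group: str = "fish_id",
    fl_column: str = "fl",
    seed: int = 0,
) -> SelectionResult:
    """Fit M0, M1 (+FL) and M1a.. (+FL + one X each) and select by AIC.

    ``candidates`` maps model suffix to covariate column, defaulting to the
    seven phenotype covariates (FR, SMR, MMR, AMS, MET1-3).  ML likelihoods
    drive the AIC/LRT comparisons; the winner is refitted by REML for its
    reported estimates.  A failed member fit is marked missing and selection
    proceeds.
    """
    if candidates is None:
        candidates = {
            "M1a": "fr",
            "M1b": "smr",
            "M1c": "mmr",
            "M1d": "ams",
            "M1e": "MET1",
            "M1f": "MET2",
            "M1g": "MET3",
        }
    y = transform_response(data[response].to_numpy(dtype=float), measure)
    df = data.copy()
    df["_y"] = y

    spec = {"M0": [], "M1": [fl_column]}
    for suffix, col in candidates.items():
        if col in df.columns:
            spec[suffix] = [fl_column, col]
        else:
            logger.warning("candidate covariate %s missing, skipped", col)

    fits: dict[str, HetVarMixedLMResults | None] = {}
    for name, covs in spec.items():
        try:
            model = HetVarMixedLM.from_dataframe(df, "_y", covs, group=group)
            fits[name] = model.fit("ml", seed=seed)
        except Exception as exc:  # noqa: BLE001 - selection must survive members
            logger.warning("fit %s failed for %s: %s", name, measure, exc)
            fits[name] = None

    rows = []
    ok = {k: v for k, v in fits.items() if v is not None}
    if not ok:
        raise ConvergenceError(f"no model converged for {measure}")
    min_aic = min(v.aic for v in ok.values())
    for name, fit in fits.items():
        row = {"model": name, "covariates": "+".join(spec[name]) or "1"}
        if fit is None:
            row.update({"loglik": np.nan, "aic": np.nan, "delta_aic": np.nan,
                        "lrt_stat": np.nan, "lrt_df": np.nan, "lrt_p": np.nan})
        else:
            nested = fits.get("M1") if name.startswith("M1") and name != "M1" else (
                fits.get("M0") if name == "M1" else None
            )
            if nested is not None:
                stat, dof, p = lrt(fit, nested)
            else:
                stat = dof = p = np.nan
            row.update(
                {
                    "loglik": fit.llf,
                    "aic": fit.aic,
                    "delta_aic": fit.aic - min_aic,
                    "lrt_stat": stat,
                    "lrt_df": dof,
                    "lrt_p": p,
                }
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    best_name = min(ok, key=lambda k: ok[k].aic)
    best_model = HetVarMixedLM.from_dataframe(df, "_y", spec[best_name], group=group)
    best_reml = best_model.fit("reml", seed=seed)
    return SelectionResult(
        measure=measure,
        table=table,
        best_name=best_name,
        best_ml=ok[best_name],
        best_reml=best_reml,
    )
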