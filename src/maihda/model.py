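"""Weighted random-intercept linear models (REML) and MAIHDA measures.

The multilevel analysis of individual heterogeneity and discriminatory
accuracy (MAIHDA) fits two consecutive two-level linear models with
individuals nested in intersectional strata:

* model 1 (simple intersectional / null model)::

      y_ij = b0 + u_j + e_ij

* model 2 (intersectional interaction model), adding fixed main effects
  of the stratum-defining dimensions (male, migration history, middle
  and low education against female / no migration / high education)::

      y_ij = b0 + b1*male + b2*migration + b3*mid_edu + b4*low_edu + u_j + e_ij

with u_j ~ N(0, sigma_u^2) and e_ij ~ N(0, sigma_e^2 / w_ij) for
individual precision-style weights w (rescaled survey weights; w = 1
recovers the unweighted model).  Estimation is restricted maximum
likelihood (REML), profiled over the variance ratio psi = su2/se2: for a
single random intercept the weighted covariance factorizes per stratum
and Sherman-Morrison reduces every REML quantity to per-stratum weighted
moments, so one criterion evaluation costs O(J p^2) after an O(n p^2)
pass.  The boundary psi = 0 is handled explicitly and flagged.

Derived measures:

* VPC = su2 / (su2 + se2) -- share of total variance between strata
  (discriminatory accuracy of the strata; the ICC);
* PCV = (su2_model1 - su2_model2) / su2_model1 -- proportion of the
  between-strata variance explained by additive main effects; 1 - PCV
  indexes residual multiplicative (intersectional) variance;
* shrunken stratum effects (BLUPs), stratum mean predictions and
  stratum-level residuals, with confidence intervals from a parametric
  bootstrap (resimulate from the fitted model, refit, re-predict;
  bootstrap-SE normal intervals by default, percentile optional).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

from .weights import rescale

__all__ = [
    "RandomInterceptREML", "MaihdaAnalysis", "VarianceDecomposition",
    "fit_reml", "vpc", "vpc_from_components", "pcv", "pcv_from_components",
    "run_sensitivity_age",
]

_TINY = 1e-300


class SingularDesignError(np.linalg.LinAlgError):
    """The fixed-effect design is rank-deficient (e.g. an indicator that is
    constant across all strata, or perfectly collinear columns)."""


def _group_moments(X, y, w, g, J):
    p = X.shape[1]
    s = np.bincount(g, weights=w, minlength=J)
    sy = np.bincount(g, weights=w * y, minlength=J)
    sx = np.zeros((J, p))
    np.add.at(sx, g, w[:, None] * X)
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * y)
    yWy = float(np.dot(w * y, y))
    sum_log_w = float(np.sum(np.log(w)))
    return s, sy, sx, XtWX, XtWy, yWy, sum_log_w


class RandomInterceptREML(RegressorMixin, BaseEstimator):
    """Linear random-intercept model estimated by (weighted) REML.

    Parameters
    ----------
    max_log10_ratio : float
        Upper search bound for log10(sigma_u^2 / sigma_e^2).  Hitting it
        is reported as non-convergence.
    xatol : float
        Absolute tolerance of the 1-d optimizer on the log10 ratio.

    Attributes (after ``fit``)
    --------------------------
    intercept_, coef_ : fixed effects (coef_ excludes the intercept)
    fe_params_, fe_names_, fe_cov_ : full fixed-effect vector with names
        and covariance (normal approximation on the REML information)
    sigma_u2_, sigma_e2_, variance_ratio_ : variance components
    ranef_ : shrunken stratum effects (BLUPs), one per group class
    group_classes_ : group labels aligned with ``ranef_``
    converged_, boundary_ : convergence / boundary flags
    loglik_restricted_ : restricted log-likelihood at the optimum
    """

    def __init__(self, max_log10_ratio: float = 6.0, xatol: float = 1e-10):
        self.max_log10_ratio = max_log10_ratio
        self.xatol = xatol

    # -- criterion -----------------------------------------------------

    @staticmethod
    def _profile(psi, s, sy, sx, XtWX, XtWy, yWy):
        """Profiled quantities at variance ratio psi.

        Returns (A, b, beta, rss, logdetA) where A = X'V^-1 X,
        b = X'V^-1 y and rss = r'V^-1 r at the profiled GLS beta, all in
        sigma_e^2 = 1 units.
        """
        c = psi / (1.0 + psi * s)
        A = XtWX - (sx * c[:, None]).T @ sx
        b = XtWy - sx.T @ (c * sy)
        q = yWy - float(np.dot(c, sy**2))
        try:
            cho = sla.cho_factor(A, lower=True)
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise SingularDesignError(str(err)) from err
        beta = sla.cho_solve(cho, b)
        rss = q - float(b @ beta)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        return A, b, beta, rss, logdetA

    def _criterion(self, psi, mom, n, p):
        s = mom[0]
        _, _, _, rss, logdetA = self._profile(psi, *mom[:-1])
        return (
            (n - p) * np.log(max(rss, _TINY))
            + float(np.sum(np.log1p(psi * s)))
            + logdetA
        )

    # -- fitting -------------------------------------------------------

    def fit(self, X, y, groups=None, sample_weight=None):
        """Fit by REML.

        Parameters
        ----------
        X : array-like (n, k) or None
            Fixed-effect design *without* the intercept (always added).
            None or zero columns gives the intercept-only null model.
        y : array-like (n,)
        groups : array-like (n,)
            Stratum labels (required).
        sample_weight : array-like (n,), optional
            Positive individual weights (precision-style).
        """
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if groups is None:
            raise ValueError("groups is required for a random-intercept model")
        if not np.all(np.isfinite(y)):
            raise ValueError("outcome contains missing or non-finite values")
        classes, g = np.unique(np.asarray(groups), return_inverse=True)
        J = classes.size
        if J < 2:
            raise ValueError(f"need >=2 strata with observations, got {J}")
        if X is None:
            Xf = np.ones((n, 1))
            names = ["intercept"]
        else:
            Xm = np.asarray(X, dtype=float)
            if Xm.ndim == 1:
                Xm = Xm[:, None]
            if not np.all(np.isfinite(Xm)):
                raise ValueError("design matrix contains missing or non-finite values")
            Xf = np.column_stack([np.ones(n), Xm])
            names = ["intercept"] + (
                list(X.columns) if isinstance(X, pd.DataFrame)
                else [f"x{i}" for i in range(Xm.shape[1])]
            )
        p = Xf.shape[1]
        if n <= p:
            raise ValueError(f"n={n} too small for {p} fixed effects")
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float).ravel()
            if np.any(w <= 0) or not np.all(np.isfinite(w)):
                raise ValueError("sample_weight must be positive and finite")

        mom = _group_moments(Xf, y, w, g, J)
        s, sy, sx, XtWX, XtWy, yWy, sum_log_w = mom

        # guard: rank-deficient design (e.g. model-2 indicator constant
        # across all strata) -- detect before optimizing
        sv = np.linalg.svd(XtWX, compute_uv=False)
        if sv[-1] <= sv[0] * 1e-12:
            raise SingularDesignError(
                "fixed-effect design is singular: a column is constant or "
                "perfectly collinear (check model-2 indicators against the strata)"
            )

        self.fe_names_ = names
        self.group_classes_ = classes
        self.nobs_, self.n_groups_ = n, J
        self._g, self._w, self._X, self._y = g, w, Xf, y
        self._s = s

        # degenerate outcome: no variation at all
        beta0 = np.linalg.solve(XtWX, XtWy)
        resid0 = y - Xf @ beta0
        if float(np.dot(w * resid0, resid0)) <= 1e-12 * max(1.0, yWy):
            self._finalize(0.0, mom, n, p, converged=True, boundary=True, degenerate=True)
            return self

        momp = mom[:-1]
        f = lambda t: self._criterion(10.0**t, mom, n, p)
        res = minimize_scalar(
            f, bounds=(-10.0, self.max_log10_ratio), method="bounded",
            options={"xatol": self.xatol},
        )
        f0 = self._criterion(0.0, mom, n, p)
        if f0 <= res.fun + 1e-9:
            psi_hat, boundary = 0.0, True
        else:
            psi_hat, boundary = 10.0**res.x, False
        converged = bool(res.success) and res.x < self.max_log10_ratio - 1e-6
        self._finalize(psi_hat, mom, n, p, converged=converged, boundary=boundary)
        return self

    def _finalize(self, psi, mom, n, p, converged, boundary, degenerate=False):
        s, sy, sx, XtWX, XtWy, yWy, sum_log_w = mom
        A, b, beta, rss, logdetA = self._profile(psi, s, sy, sx, XtWX, XtWy, yWy)
        if degenerate:
            sigma_e2 = 0.0
        else:
            sigma_e2 = max(rss, 0.0) / (n - p)
        sigma_u2 = psi * sigma_e2
        self.variance_ratio_ = float(psi)
        self.sigma_e2_ = float(sigma_e2)
        self.sigma_u2_ = float(sigma_u2)
        self.fe_params_ = beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        Ainv = sla.cho_solve(sla.cho_factor(A, lower=True), np.eye(p))
        self.fe_cov_ = sigma_e2 * Ainv
        resid_fe = sy - sx @ beta  # per-group weighted residual sums
        self.ranef_ = psi * resid_fe / (1.0 + psi * s)
        self.converged_ = bool(converged)
        self.boundary_ = bool(boundary)
        if degenerate or sigma_e2 <= 0.0:
            self.loglik_restricted_ = np.nan
        else:
            log_det_V = float(np.sum(np.log1p(psi * s))) - sum_log_w
            self.loglik_restricted_ = -0.5 * (
                (n - p) * (np.log(2.0 * np.pi) + 1.0)
                + (n - p) * np.log(sigma_e2)
                + log_det_V
                + logdetA
            )

    # -- post-fit API --------------------------------------------------

    def fe_confint(self, level: float = 0.95) -> pd.DataFrame:
        """Normal-approximation confidence intervals for the fixed effects."""
        z = norm.ppf(0.5 + level / 2.0)
        se = np.sqrt(np.diag(self.fe_cov_))
        return pd.DataFrame(
            {"estimate": self.fe_params_, "se": se,
             "lo": self.fe_params_ - z * se, "hi": self.fe_params_ + z * se},
            index=self.fe_names_,
        )

    def ranef_series(self) -> pd.Series:
        return pd.Series(self.ranef_, index=self.group_classes_, name="u_hat")

    def predict(self, X, groups=None, basis: str = "total") -> np.ndarray:
        """Predict outcomes; ``basis`` is "fixed" or "total" (+ BLUP)."""
        if X is None:
            n = len(np.asarray(groups)) if groups is not None else 1
            lp = np.full(n, self.intercept_)
        else:
            Xm = np.asarray(X, dtype=float)
            if Xm.ndim == 1:
                Xm = Xm[:, None]
            lp = self.intercept_ + Xm @ self.coef_
        if basis == "fixed":
            return lp
        if basis != "total":
            raise ValueError(f"basis must be 'fixed' or 'total', got {basis!r}")
        if groups is None:
            raise ValueError("groups required for basis='total'")
        idx = {c: i for i, c in enumerate(self.group_classes_)}
        u = np.array([self.ranef_[idx[gv]] for gv in np.asarray(groups)])
        return lp + u

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one outcome vector from the fitted model (parametric
        bootstrap: new stratum effects, new individual residuals)."""
        u_star = rng.normal(0.0, np.sqrt(self.sigma_u2_), self.n_groups_)
        e_star = rng.normal(0.0, np.sqrt(self.sigma_e2_ / self._w))
        return self._X @ self.fe_params_ + u_star[self._g] + e_star

    def refit_to(self, y_star: np.ndarray) -> "RandomInterceptREML":
        """Fit a fresh model with the same design/groups/weights to new y."""
        clone = RandomInterceptREML(self.max_log10_ratio, self.xatol)
        Xsub = self._X[:, 1:] if self._X.shape[1] > 1 else None
        clone.fit(Xsub, y_star, groups=self._g, sample_weight=self._w)
        clone.fe_names_ = self.fe_names_
        clone.group_classes_ = self.group_classes_
        return clone


# ---------------------------------------------------------------------------
# measures


def vpc_from_components(sigma_u2: float, sigma_e2: float) -> float:
    """Variance partition coefficient su2/(su2+se2), as a fraction."""
    total = sigma_u2 + sigma_e2
    if total <= 0:
        raise ValueError("VPC undefined: sigma_u2 + sigma_e2 = 0")
    return float(sigma_u2 / total)


def vpc(fit: RandomInterceptREML) -> float:
    """VPC of a fitted model (fraction of total variance between strata)."""
    return vpc_from_components(fit.sigma_u2_, fit.sigma_e2_)


def pcv_from_components(sigma_u2_model1: float, sigma_u2_model2: float) -> tuple[float, float]:
    """Proportional change in between-strata variance, (PCV, 1-PCV).

    May be negative if the adjusted model increases the between-strata
    variance; reported as-is, never clamped.
    """
    if sigma_u2_model1 <= 0:
        raise ValueError("PCV undefined: null-model between-strata variance is 0")
    p = float((sigma_u2_model1 - sigma_u2_model2) / sigma_u2_model1)
    return p, 1.0 - p


def pcv(fit1: RandomInterceptREML, fit2: RandomInterceptREML) -> tuple[float, float]:
    if fit1.nobs_ != fit2.nobs_ or fit1.n_groups_ != fit2.n_groups_:
        raise ValueError("PCV requires both models fitted to identical data and grouping")
    return pcv_from_components(fit1.sigma_u2_, fit2.sigma_u2_)


@dataclass(frozen=True)
class VarianceDecomposition:
    """VPC of both models plus PCV / 1-PCV between them (fractions)."""

    vpc_model1: float
    vpc_model2: float
    pcv: float
    one_minus_pcv: float

    def as_percent(self) -> dict:
        return {
            "vpc_model1_pct": round(100 * self.vpc_model1, 2),
            "vpc_model2_pct": round(100 * self.vpc_model2, 2),
            "pcv_pct": round(100 * self.pcv, 2),
            "one_minus_pcv_pct": round(100 * self.one_minus_pcv, 2),
        }


# ---------------------------------------------------------------------------
# orchestration


def _design_model2(df, sex_col, education_col, migration_col, reference, age_col=None):
    ref_sex, ref_edu, ref_mig = reference
    sex_lv = [c for c in pd.unique(df[sex_col]) if c != ref_sex]
    mig_lv = [c for c in pd.unique(df[migration_col]) if c != ref_mig]
    edu_lv = [c for c in pd.unique(df[education_col]) if c != ref_edu]
    cols = {}
    for lv in sex_lv:
        cols[str(lv)] = (df[sex_col] == lv).astype(float)
    for lv in mig_lv:
        cols[f"migration_{lv}"] = (df[migration_col] == lv).astype(float)
    for lv in edu_lv:
        cols[f"education_{lv}"] = (df[education_col] == lv).astype(float)
    if age_col is not None:
        cols["age"] = pd.to_numeric(df[age_col], errors="raise").astype(float)
    return pd.DataFrame(cols, index=df.index)


class MaihdaAnalysis(BaseEstimator):
    """End-to-end MAIHDA on a records frame: both models plus measures.

    Fits the null model (model 1) and the main-effects-adjusted model
    (model 2) by weighted REML, and exposes the variance decomposition,
    bootstrap stratum-mean predictions and stratum-level residuals.

    Parameters
    ----------
    outcome_col, stratum_col, sex_col, education_col, migration_col,
    weight_col, age_col : column names in the input frame.
    reference : (sex, education, migration) reference categories.
    include_age : add age (years, continuous) as a fixed term in both
        models -- the age-adjusted sensitivity variant.
    rescale_method : survey-weight rescaling method (see weights module).
    n_boot : default parametric-bootstrap replicates for CIs.
    ci_method : "boot_se_normal" (bootstrap SE, normal interval centred
        on the point estimate; matches bootstrapped standard errors of
        predicted means) or "percentile".
    random_state : seed for all bootstrap resampling.
    """

    def __init__(
        self,
        outcome_col: str = "gdrs_points",
        stratum_col: str = "stratum_id",
        sex_col: str = "sex_gender",
        education_col: str = "education",
        migration_col: str = "migration",
        weight_col: str | None = None,
        age_col: str = "age",
        reference: tuple = ("female", "high", "no"),
        include_age: bool = False,
        rescale_method: str = "mean_one",
        n_boot: int = 1000,
        ci_method: str = "boot_se_normal",
        random_state: int = 0,
    ):
        self.outcome_col = outcome_col
        self.stratum_col = stratum_col
        self.sex_col = sex_col
        self.education_col = education_col
        self.migration_col = migration_col
        self.weight_col = weight_col
        self.age_col = age_col
        self.reference = reference
        self.include_age = include_age
        self.rescale_method = rescale_method
        self.n_boot = n_boot
        self.ci_method = ci_method
        self.random_state = random_state

    # -- fitting -------------------------------------------------------

    def fit(self, df: pd.DataFrame, y=None):
        if df[self.outcome_col].isna().any():
            raise ValueError(f"outcome column {self.outcome_col!r} has missing values")
        self._df = df
        w = None
        if self.weight_col is not None:
            w = rescale(df[self.weight_col].to_numpy(), self.rescale_method)
        self.weights_ = w
        groups = df[self.stratum_col].to_numpy()
        y = df[self.outcome_col].to_numpy(dtype=float)

        age = self.age_col if self.include_age else None
        X1 = (
            _design_model2(df, self.sex_col, self.education_col, self.migration_col,
                           self.reference, age_col=self.age_col)[["age"]]
            if self.include_age else None
        )
        X2 = _design_model2(
            df, self.sex_col, self.education_col, self.migration_col,
            self.reference, age_col=age,
        )
        self.model1_ = RandomInterceptREML().fit(X1, y, groups=groups, sample_weight=w)
        self.model2_ = RandomInterceptREML().fit(X2, y, groups=groups, sample_weight=w)
        self._X1, self._X2 = X1, X2

        p, omp = pcv(self.model1_, self.model2_)
        self.decomposition_ = VarianceDecomposition(
            vpc_model1=vpc(self.model1_), vpc_model2=vpc(self.model2_),
            pcv=p, one_minus_pcv=omp,
        )

        # per-stratum design rows (weighted means; exact for columns that
        # are constant within stratum, i.e. everything except age)
        self.stratum_ids_ = self.model1_.group_classes_
        self._stratum_rows = {}
        for key, X in (("model1", X1), ("model2", X2)):
            if X is None:
                self._stratum_rows[key] = None
                continue
            Xv = X.to_numpy(dtype=float)
            wv = np.ones(len(df)) if w is None else w
            g = pd.Series(groups, index=df.index)
            num = np.zeros((len(self.stratum_ids_), Xv.shape[1]))
            den = np.zeros(len(self.stratum_ids_))
            gi = {c: i for i, c in enumerate(self.stratum_ids_)}
            for row, gv, wt in zip(Xv, groups, wv):
                num[gi[gv]] += wt * row
                den[gi[gv]] += wt
            self._stratum_rows[key] = num / den[:, None]
        self._boot_cache = {}
        return self

    # -- bootstrap machinery -------------------------------------------

    def _bootstrap(self, model_key: str, B: int):
        """Parametric bootstrap of one model; cached per (model, B).

        Returns dict of stacked arrays: fe (B,p), su2 (B,), se2 (B,),
        uhat (B,J).
        """
        if B < 2:
            raise ValueError("bootstrap needs B >= 2 replicates")
        key = (model_key, B)
        if key in self._boot_cache:
            return self._boot_cache[key]
        model = self.model1_ if model_key == "model1" else self.model2_
        tag = 1 if model_key == "model1" else 2
        rng = np.random.default_rng([self.random_state, tag])
        fe, su2, se2, uhat = [], [], [], []
        for _ in range(B):
            y_star = model.simulate(rng)
            refit = model.refit_to(y_star)
            fe.append(refit.fe_params_)
            su2.append(refit.sigma_u2_)
            se2.append(refit.sigma_e2_)
            uhat.append(refit.ranef_)
        out = {
            "fe": np.array(fe), "su2": np.array(su2),
            "se2": np.array(se2), "uhat": np.array(uhat),
        }
        self._boot_cache[key] = out
        return out

    @staticmethod
    def _pctl(arr, axis=0):
        lo, hi = np.percentile(arr, [2.5, 97.5], axis=axis)
        return lo, hi

    @staticmethod
    def _ci(point, reps, method: str):
        """95% CI from bootstrap replicates.

        ``boot_se_normal`` (default): point +/- z * SD(replicates) -- the
        bootstrap estimates the standard error of the prediction and the
        interval is centred on the point estimate.  Because the
        parametric bootstrap redraws stratum effects from N(0, su2),
        replicate predictions fluctuate around the population level, not
        around the stratum's conditional estimate; a percentile interval
        of the raw replicates would therefore not be centred on the
        point prediction and could never flag an outlying stratum.
        ``percentile``: raw 2.5/97.5 percentiles of the replicates.
        """
        if method == "percentile":
            return MaihdaAnalysis._pctl(reps)
        if method != "boot_se_normal":
            raise ValueError(f"unknown ci_method {method!r}")
        z = norm.ppf(0.975)
        sd = reps.std(axis=0, ddof=1)
        return point - z * sd, point + z * sd

    def _stratum_lp(self, model_key: str, fe: np.ndarray) -> np.ndarray:
        """Per-stratum fixed-effect linear predictor rows @ fe params."""
        rows = self._stratum_rows[model_key]
        if rows is None:
            return np.full(len(self.stratum_ids_), fe[..., 0]).T if fe.ndim == 1 else (
                np.tile(fe[:, :1], (1, len(self.stratum_ids_))))
        if fe.ndim == 1:
            return fe[0] + rows @ fe[1:]
        return fe[:, :1] + fe[:, 1:] @ rows.T  # (B, J)

    def stratum_predictions(
        self, basis: str = "model1_total", n_boot: int | None = None
    ) -> pd.DataFrame:
        """Predicted stratum means with parametric-bootstrap 95% CIs.

        ``basis``: "model1_total" (null-model prediction, the headline
        stratum means), "model2_fixed" (additive main effects only) or
        "model2_total" (main effects + shrunken stratum effect).
        """
        B = self.n_boot if n_boot is None else n_boot
        model_key = "model1" if basis.startswith("model1") else "model2"
        model = self.model1_ if model_key == "model1" else self.model2_
        boot = self._bootstrap(model_key, B)
        point_fixed = self._stratum_lp(model_key, model.fe_params_)
        boot_fixed = self._stratum_lp(model_key, boot["fe"])
        if basis.endswith("_fixed"):
            point, reps = point_fixed, boot_fixed
        else:
            point = point_fixed + model.ranef_
            reps = boot_fixed + boot["uhat"]
        lo, hi = self._ci(point, reps, self.ci_method)
        n_by = pd.Series(self._df[self.stratum_col]).value_counts()
        return pd.DataFrame({
            "stratum_id": self.stratum_ids_,
            "n": [int(n_by.get(sid, 0)) for sid in self.stratum_ids_],
            "predicted_mean": point, "ci_lo": lo, "ci_hi": hi,
            "basis": basis,
        })

    def stratum_residuals(self, n_boot: int | None = None) -> pd.DataFrame:
        """Stratum-level residuals (model-2 total minus additive
        prediction = shrunken stratum effect) with bootstrap 95% CIs and
        a flag for CIs excluding 0 (evidence of a multiplicative
        intersectional effect in that stratum)."""
        B = self.n_boot if n_boot is None else n_boot
        boot = self._bootstrap("model2", B)
        point = self.model2_.ranef_
        lo, hi = self._ci(point, boot["uhat"], self.ci_method)
        return pd.DataFrame({
            "stratum_id": self.stratum_ids_,
            "residual": point, "ci_lo": lo, "ci_hi": hi,
            "ci_excludes_zero": (lo > 0) | (hi < 0),
        })

    def variance_component_cis(self, model_key: str = "model1", n_boot: int | None = None) -> dict:
        """Percentile bootstrap 95% CIs for sigma_u^2 and sigma_e^2."""
        B = self.n_boot if n_boot is None else n_boot
        boot = self._bootstrap(model_key, B)
        lo_u, hi_u = self._pctl(boot["su2"])
        lo_e, hi_e = self._pctl(boot["se2"])
        return {"sigma_u2": (float(lo_u), float(hi_u)), "sigma_e2": (float(lo_e), float(hi_e))}


# ---------------------------------------------------------------------------
# functional wrappers


def fit_reml(
    df: pd.DataFrame,
    outcome: str,
    fixed_terms: pd.DataFrame | None,
    stratum_col: str = "stratum_id",
    sample_weight=None,
) -> RandomInterceptREML:
    """Fit one weighted random-intercept model (thin functional wrapper)."""
    return RandomInterceptREML().fit(
        fixed_terms, df[outcome].to_numpy(dtype=float),
        groups=df[stratum_col].to_numpy(), sample_weight=sample_weight,
    )


def run_sensitivity_age(df: pd.DataFrame, **params) -> dict:
    """Main analysis and the age-adjusted variant, side by side.

    Returns {"main": MaihdaAnalysis, "age_adjusted": MaihdaAnalysis,
    "comparison": tidy DataFrame of the headline measures}.
    """
    main = MaihdaAnalysis(**params).fit(df)
    aged = MaihdaAnalysis(**{**params, "include_age": True}).fit(df)
    rows = []
    for label, an in (("main", main), ("age_adjusted", aged)):
        d = an.decomposition_.as_percent()
        rows.append({
            "analysis": label, **d,
            "sigma_u2_model1": an.model1_.sigma_u2_,
            "sigma_u2_model2": an.model2_.sigma_u2_,
            "sigma_e2_model2": an.model2_.sigma_e2_,
            **{f"beta_{nm}": v for nm, v in
               zip(an.model2_.fe_names_, an.model2_.fe_params_)},
        })
    return {"main": main, "age_adjusted": aged, "comparison": pd.DataFrame(rows)}
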