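"""Nested linear mixed model with patient and focus random intercepts.

The model for one gene's log2 expression is

    y = X beta + Z_P a + Z_F b + e,
    a ~ N(0, sigma_P^2 I),  b ~ N(0, sigma_F^2 I),  e ~ N(0, sigma_IT^2 I),

with focus levels nested within patient levels.  The three standard
deviations partition variability into patient-to-patient (sigma_P),
between-foci-within-patient (sigma_F) and residual punch-to-punch
(sigma_IT) components.

Estimation maximizes the Gaussian likelihood (ML) or the restricted
likelihood (REML).  Internally the criterion is profiled over beta (by GLS)
and over the residual variance, leaving a 2-D problem in the variance
ratios gamma_P = sigma_P^2/sigma_IT^2 and gamma_F = sigma_F^2/sigma_IT^2,
optimized by L-BFGS-B from a fixed 3x3 multi-start grid that includes the
gamma = 0 boundary, so boundary solutions (sigma_hat = 0) are reached
deterministically.

Likelihood-ratio tests for H0: sigma_F = 0 (or sigma_P = 0) sit on the
boundary of the parameter space; both the naive chi-square(1) reference and
the 50:50 mixture of chi-square(0) and chi-square(1) are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "NestedLMM",
    "NestedLMMResults",
    "AliasingWarning",
    "reml_criterion",
    "lrt_variance_component",
    "lrt_focus_variance",
]

_LOG2PI = np.log(2.0 * np.pi)

#: fixed multi-start grid over the variance ratios (includes the boundary)
_START_GRID = (0.0, 1.0, 4.0)


class AliasingWarning(UserWarning):
    """Variance components are not separately identifiable in this design."""


def _indicator(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels, inv = np.unique(labels, return_inverse=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), inv] = 1.0
    return Z, list(levels)


class NestedLMM:
    """Linear mixed model with nested patient/focus random intercepts.

    Parameters
    ----------
    endog : array-like
        Response vector (log2 expression values).
    exog : array-like
        Fixed-effect design matrix, full column rank.
    patient : sequence
        Patient label per observation.
    focus : sequence
        Focus label per observation; must determine the patient label.
        Labels need only be unique within patient (they are combined with
        the patient label internally).
    exog_names : sequence of str, optional
        Column names for the fixed design.
    """

    def __init__(self, endog, exog, patient, focus, exog_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = len(y)
        if X.shape[0] != n:
            raise ValueError("endog and exog have different lengths")
        patient = np.asarray([str(p) for p in patient])
        focus = np.asarray([str(f) for f in focus])
        if len(patient) != n or len(focus) != n:
            raise ValueError("patient/focus labels must match endog length")
        # focus labels are only meaningful within a patient
        combined = np.array([f"{p}::{f}" for p, f in zip(patient, focus)])
        # nesting check: a raw focus label used by two patients is treated as
        # distinct per patient by the combination above, which also catches
        # genuinely inconsistent label maps
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design matrix is rank deficient")
        if len(np.unique(patient)) < 2:
            raise ValueError("at least 2 patients are required")
        self.endog = y
        self.exog = X
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(X.shape[1])]
        )
        self.patient_labels = patient
        self.focus_labels = combined
        self.Z_patient, self.patient_levels = _indicator(patient)
        self.Z_focus, self.focus_levels = _indicator(combined)
        self._A = self.Z_patient @ self.Z_patient.T
        self._B = self.Z_focus @ self.Z_focus.T
        self.nobs = n
        self.k_fixed = X.shape[1]
        self._check_aliasing()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        fixed: tuple[str, ...] = (),
        patient: str = "patient_id",
        focus: str = "focus_id",
    ) -> "NestedLMM":
        """Build a model from a tidy frame, dummy-coding categorical effects."""
        y = data[response]
        cols = [np.ones(len(data))]
        names = ["Intercept"]
        for c in fixed:
            col = data[c]
            if col.dtype.kind in "fiu" and col.nunique() > 2:
                cols.append(col.to_numpy(dtype=float))
                names.append(c)
            else:
                dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
                for d in dummies.columns:
                    cols.append(dummies[d].to_numpy(dtype=float))
                    names.append(d)
        X = np.column_stack(cols)
        return cls(y, X, data[patient], data[focus], exog_names=names)

    # ------------------------------------------------------------------
    def _check_aliasing(self) -> None:
        focus_sizes = self.Z_focus.sum(axis=0)
        if np.all(focus_sizes == 1):
            warnings.warn(
                "every focus has a single observation: sigma_F and sigma_IT "
                "are not separately identifiable",
                AliasingWarning,
                stacklevel=3,
            )
        pat_foci = {}
        for p, f in zip(self.patient_labels, self.focus_labels):
            pat_foci.setdefault(p, set()).add(f)
        if all(len(v) == 1 for v in pat_foci.values()):
            warnings.warn(
                "every patient has a single focus: sigma_P and sigma_F "
                "are not separately identifiable",
                AliasingWarning,
                stacklevel=3,
            )

    # ------------------------------------------------------------------
    def loglike(self, sigmas, method: str = "REML") -> float:
        """Exact (restricted) log-likelihood at fixed standard deviations.

        Evaluates the marginal covariance V = sigma_P^2 Z_P Z_P' +
        sigma_F^2 Z_F Z_F' + sigma_IT^2 I directly, with beta profiled out
        by GLS; the REML criterion includes the -1/2 log|X' V^-1 X| term.
        """
        sP, sF, sIT = (float(s) for s in sigmas)
        if min(sP, sF, sIT) < 0:
            raise ValueError("standard deviations must be non-negative")
        method = _check_method(method)
        n, p = self.nobs, self.k_fixed
        V = sIT**2 * np.eye(n) + sP**2 * self._A + sF**2 * self._B
        try:
            c = cho_factor(V, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular covariance matrix V") from exc
        if not np.all(np.isfinite(np.diag(c[0]))) or np.any(
            np.diag(c[0]) <= 0
        ):
            raise ValueError("singular covariance matrix V")
        logdet_V = 2.0 * np.sum(np.log(np.diag(c[0])))
        Vi_X = cho_solve(c, self.exog)
        Vi_y = cho_solve(c, self.endog)
        XtViX = self.exog.T @ Vi_X
        beta = np.linalg.solve(XtViX, self.exog.T @ Vi_y)
        r = self.endog - self.exog @ beta
        quad = float(r @ cho_solve(c, r))
        if method == "ML":
            return -0.5 * (n * _LOG2PI + logdet_V + quad)
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise ValueError("X' V^-1 X not positive definite")
        return -0.5 * ((n - p) * _LOG2PI + logdet_V + logdet_XtViX + quad)

    # ------------------------------------------------------------------
    def _profiled(self, gP: float, gF: float, reml: bool,
                  use_patient: bool, use_focus: bool):
        """Criterion profiled over beta and the residual variance.

        Returns (criterion value, beta, s2_IT, XtWiX_inv) where W = I +
        gP*A + gF*B and s2_IT is the profiled residual variance.
        """
        n, p = self.nobs, self.k_fixed
        W = np.eye(n)
        if use_patient:
            W += gP * self._A
        if use_focus:
            W += gF * self._B
        c = cho_factor(W, lower=True)
        logdet_W = 2.0 * np.sum(np.log(np.diag(c[0])))
        Wi_X = cho_solve(c, self.exog)
        Wi_y = cho_solve(c, self.endog)
        XtWiX = self.exog.T @ Wi_X
        beta = np.linalg.solve(XtWiX, self.exog.T @ Wi_y)
        r = self.endog - self.exog @ beta
        q = float(r @ cho_solve(c, r))
        df = n - p if reml else n
        s2 = max(q / df, 1e-30)
        # with V = s2*W: log|V| = n log s2 + log|W| and log|X'V^-1 X| =
        # log|X'W^-1 X| - p log s2, so the log s2 terms collapse to df*log s2
        crit = df * (_LOG2PI + np.log(s2)) + logdet_W + df
        if reml:
            sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
            crit += logdet_XtWiX
        return -0.5 * crit, beta, s2, XtWiX

    def fit(
        self,
        method: str = "REML",
        include_patient: bool = True,
        include_focus: bool = True,
        maxiter: int = 500,
        tol: float = 1e-8,
    ) -> "NestedLMMResults":
        """Fit by (restricted) maximum likelihood.

        ``include_patient`` / ``include_focus`` drop the corresponding
        variance component (fixing its sigma at 0), which is how the
        reduced models for the boundary LRTs are fitted.
        """
        method = _check_method(method)
        reml = method == "REML"

        free = []
        if include_patient:
            free.append("P")
        if include_focus:
            free.append("F")

        def negcrit(x):
            gP = x[free.index("P")] if "P" in free else 0.0
            gF = x[free.index("F")] if "F" in free else 0.0
            return -self._profiled(gP, gF, reml, include_patient, include_focus)[0]

        converged = True
        n_iter = 0
        if not free:
            best_x = np.zeros(0)
        else:
            starts = (
                [(a, b) for a in _START_GRID for b in _START_GRID]
                if len(free) == 2
                else [(a,) for a in _START_GRID]
            )
            best_x, best_val, best_ok = None, np.inf, False
            for s in starts:
                res = optimize.minimize(
                    negcrit,
                    x0=np.asarray(s, dtype=float),
                    method="L-BFGS-B",
                    bounds=[(0.0, None)] * len(free),
                    options={"maxiter": maxiter, "ftol": tol * 1e-2,
                             "gtol": tol},
                )
                n_iter += res.nit
                if res.fun < best_val - 1e-12 or best_x is None:
                    best_x, best_val, best_ok = res.x, res.fun, res.success
            converged = bool(best_ok)

        gP = best_x[free.index("P")] if "P" in free else 0.0
        gF = best_x[free.index("F")] if "F" in free else 0.0
        crit, beta, s2, XtWiX = self._profiled(
            gP, gF, reml, include_patient, include_focus
        )
        sigma_IT = float(np.sqrt(s2))
        sigma_P = float(np.sqrt(gP * s2)) if include_patient else 0.0
        sigma_F = float(np.sqrt(gF * s2)) if include_focus else 0.0
        # snap numerically-zero boundary estimates exactly to the boundary
        tot = sigma_P**2 + sigma_F**2 + sigma_IT**2
        if tot > 0:
            if sigma_P**2 < 1e-10 * tot:
                sigma_P = 0.0
            if sigma_F**2 < 1e-10 * tot:
                sigma_F = 0.0
        cov_beta = s2 * np.linalg.inv(XtWiX)
        return NestedLMMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(
                cov_beta, index=self.exog_names, columns=self.exog_names
            ),
            sigma_P=sigma_P,
            sigma_F=sigma_F,
            sigma_IT=sigma_IT,
            llf=float(crit),
            method=method,
            converged=converged,
            include_patient=include_patient,
            include_focus=include_focus,
            n_iter=int(n_iter),
        )


def _check_method(method: str) -> str:
    m = method.upper()
    if m not in ("ML", "REML"):
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
    return m


@dataclass
class NestedLMMResults:
    """Fit results: fixed effects, variance components and the criterion."""

    model: NestedLMM
    params: pd.Series
    cov_params: pd.DataFrame
    sigma_P: float
    sigma_F: float
    sigma_IT: float
    llf: float
    method: str
    converged: bool
    include_patient: bool = True
    include_focus: bool = True
    n_iter: int = 0

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params)), index=self.params.index
        )

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    def pvalues(self, use_t: bool = False) -> pd.Series:
        """Wald p-values for the fixed effects.

        The default uses a normal reference; ``use_t=True`` uses a t
        reference with a Satterthwaite-style residual df proxy
        (n - rank(X) - number of random-effect levels).
        """
        t = self.tvalues
        if use_t:
            df = max(
                self.model.nobs
                - self.model.k_fixed
                - len(self.model.focus_levels),
                1,
            )
            p = 2 * stats.t.sf(np.abs(t), df)
        else:
            p = 2 * stats.norm.sf(np.abs(t))
        return pd.Series(p, index=self.params.index)

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "patient": self.sigma_P**2,
            "focus": self.sigma_F**2,
            "residual": self.sigma_IT**2,
        }

    def summary(self) -> str:
        lines = [
            "Nested linear mixed model "
            f"({self.method}, {'converged' if self.converged else 'NOT converged'})",
            f"  observations: {self.model.nobs}   patients: "
            f"{len(self.model.patient_levels)}   foci: "
            f"{len(self.model.focus_levels)}",
            f"  log-likelihood ({self.method}): {self.llf:.4f}",
            "",
            "  Fixed effects        coef     std err        z      P>|z|",
        ]
        pv = self.pvalues()
        for name in self.params.index:
            lines.append(
                f"  {name:<16} {self.params[name]:>9.4f} {self.bse[name]:>11.4f} "
                f"{self.tvalues[name]:>8.3f} {pv[name]:>10.3g}"
            )
        lines += [
            "",
            "  Random effects (std dev)",
            f"    patient   sigma_P  = {self.sigma_P:.4f}",
            f"    focus     sigma_F  = {self.sigma_F:.4f}",
            f"    residual  sigma_IT = {self.sigma_IT:.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# free-function surface
# ---------------------------------------------------------------------------

def reml_criterion(sigmas, spec: NestedLMM, method: str = "REML") -> float:
    """Exact (restricted) log-likelihood at fixed (sigma_P, sigma_F, sigma_IT).

    This is the non-profiled evaluation used as the independent surface for
    checking :meth:`NestedLMM.fit`; it shares no optimizer code.
    """
    return spec.loglike(sigmas, method=method)


def lrt_variance_component(
    full: NestedLMMResults,
    reduced: NestedLMMResults,
    convention: str = "chisq1",
) -> float:
    """Boundary likelihood-ratio p-value for dropping one variance component.

    ``chisq1`` refers 2*(llf_full - llf_reduced) to chi-square(1);
    ``mixture_half`` halves the tail probability (50:50 mixture of a point
    mass at 0 and chi-square(1)), returning 1 when the statistic is 0.
    """
    if full.method != reduced.method:
        raise ValueError("full and reduced fits use different methods")
    if full.model.k_fixed != reduced.model.k_fixed or not np.allclose(
        full.model.exog, reduced.model.exog
    ):
        raise ValueError("full and reduced fits have different fixed designs")
    dropped = (full.include_patient and not reduced.include_patient) or (
        full.include_focus and not reduced.include_focus
    )
    if not dropped:
        raise ValueError("reduced fit does not drop a variance component")
    lam = 2.0 * (full.llf - reduced.llf)
    lam = max(lam, 0.0)
    if convention == "chisq1":
        return float(stats.chi2.sf(lam, 1))
    if convention == "mixture_half":
        if lam == 0.0:
            return 1.0
        return float(0.5 * stats.chi2.sf(lam, 1))
    raise ValueError(f"unknown LRT convention {convention!r}")


def lrt_focus_variance(
    full: NestedLMMResults,
    reduced: NestedLMMResults,
    convention: str = "chisq1",
) -> float:
    """LRT p-value for H0: sigma_F = 0 (between-foci heterogeneity absent)."""
    if not full.include_focus or reduced.include_focus:
        raise ValueError(
            "expected a full fit with the focus component and a reduced fit "
            "with sigma_F fixed at 0"
        )
    return lrt_variance_component(full, reduced, convention)
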