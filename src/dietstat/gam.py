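"""Gaussian additive-model engine: penalized regression splines with REML.

This module is the numerical boundary of the stomach-weight modelling stage.
It fits models of the form

    y = beta0 + (factor offsets) + sum_j f_j(x_j) + eps,   eps ~ N(0, sigma^2)

where each ``f_j`` is a penalized B-spline (P-spline: cubic B-spline basis on
equally spaced knots, second-order difference penalty) and the two
geographic coordinates may enter jointly as an isotropic tensor-product
surface.  Smoothing parameters are chosen by restricted maximum likelihood:
for the Gaussian/identity case the profiled REML score is

    V(lambda) = (n - M) log(RSS_p) + log|X'X + S(lambda)| - log|S(lambda)|_+

with RSS_p the penalized residual sum of squares, S the block-diagonal
penalty, M the number of unpenalized coefficient directions and |.|_+ the
pseudo-determinant; V is minimized over log-lambda with a derivative-free
simplex search.  Effective degrees of freedom are tr((X'X + S)^-1 X'X) and
AIC is the conditional Gaussian AIC, -2 loglik + 2 (edf + 1), counting the
scale parameter.

Smooth-term significance is a Wald-type approximation: the quadratic form of
the term's coefficients in the inverse of their posterior covariance,
referred to an F distribution on (edf_j, n - edf_total) degrees of freedom.
It is reported as approximate, which is how such tests should be read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .errors import ConfigurationError, ValidationError

_EIG_TOL = 1e-9


# ---------------------------------------------------------------------------
# basis construction
# ---------------------------------------------------------------------------


def _bspline_design(x: np.ndarray, lo: float, hi: float, k: int, degree: int = 3):
    """Design matrix of a k-column B-spline basis on equally spaced knots."""
    if k <= degree:
        raise ValidationError(f"basis dimension k={k} must exceed degree {degree}")
    n_inner = k - degree + 1
    if hi <= lo:
        hi = lo + 1.0  # degenerate covariate: constant column range
    inner = np.linspace(lo, hi, n_inner)
    step = inner[1] - inner[0]
    knots = np.concatenate(
        [inner[0] - step * np.arange(degree, 0, -1), inner,
         inner[-1] + step * np.arange(1, degree + 1)]
    )
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray(), knots


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _centering_transform(B: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the sum-to-zero constraint null space.

    Columns of B @ Z average to zero over the data, removing the confounding
    of every smooth with the model intercept.
    """
    c = B.mean(axis=0, keepdims=True)  # 1 x k
    # householder-style: null space of c via full QR of c'
    q, _ = np.linalg.qr(c.T, mode="complete")
    return q[:, 1:]


@dataclass
class SmoothTerm:
    """A one-dimensional P-spline term s(var) with basis dimension k."""

    var: str
    k: int = 10
    degree: int = 3

    # fitted-state fields, populated by the design builder
    _lo: float = field(default=0.0, repr=False)
    _hi: float = field(default=1.0, repr=False)
    _Z: np.ndarray | None = field(default=None, repr=False)

    @property
    def label(self) -> str:
        return f"s({self.var})"

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.var,)

    def build(self, data: pd.DataFrame):
        x = data[self.var].to_numpy(dtype=float)
        self._lo, self._hi = float(np.min(x)), float(np.max(x))
        B, _ = _bspline_design(x, self._lo, self._hi, self.k, self.degree)
        S = _difference_penalty(self.k)
        self._Z = _centering_transform(B)
        return B @ self._Z, self._Z.T @ S @ self._Z

    def basis_at(self, x: np.ndarray) -> np.ndarray:
        B, _ = _bspline_design(
            np.asarray(x, dtype=float), self._lo, self._hi, self.k, self.degree
        )
        return B @ self._Z


@dataclass
class TensorSmooth:
    """An isotropic 2-D tensor-product P-spline surface s(var_x, var_y).

    Marginal cubic B-spline bases of dimension k are combined row-wise by the
    Kronecker product; the penalty is the Kronecker sum of the marginal
    second-difference penalties under a single smoothing parameter, which
    penalizes roughness equally in both directions (appropriate for a
    longitude-latitude surface over a survey-scale region).
    """

    var_x: str
    var_y: str
    k: int = 5
    degree: int = 3

    _lims: tuple = field(default=(0, 1, 0, 1), repr=False)
    _Z: np.ndarray | None = field(default=None, repr=False)

    @property
    def label(self) -> str:
        return f"s({self.var_x},{self.var_y})"

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.var_x, self.var_y)

    def build(self, data: pd.DataFrame):
        x = data[self.var_x].to_numpy(dtype=float)
        y = data[self.var_y].to_numpy(dtype=float)
        self._lims = (float(x.min()), float(x.max()), float(y.min()), float(y.max()))
        Bx, _ = _bspline_design(x, self._lims[0], self._lims[1], self.k, self.degree)
        By, _ = _bspline_design(y, self._lims[2], self._lims[3], self.k, self.degree)
        B = np.einsum("ni,nj->nij", Bx, By).reshape(len(x), -1)
        Sx = _difference_penalty(self.k)
        Sy = _difference_penalty(self.k)
        S = np.kron(Sx, np.eye(self.k)) + np.kron(np.eye(self.k), Sy)
        self._Z = _centering_transform(B)
        return B @ self._Z, self._Z.T @ S @ self._Z

    def basis_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        Bx, _ = _bspline_design(
            np.asarray(x, float), self._lims[0], self._lims[1], self.k, self.degree
        )
        By, _ = _bspline_design(
            np.asarray(y, float), self._lims[2], self._lims[3], self.k, self.degree
        )
        B = np.einsum("ni,nj->nij", Bx, By).reshape(len(np.asarray(x)), -1)
        return B @ self._Z


# ---------------------------------------------------------------------------
# the fit
# ---------------------------------------------------------------------------


@dataclass
class GamFit:
    """A fitted Gaussian additive model."""

    beta: np.ndarray
    cov: np.ndarray  # posterior covariance sigma2 * (X'X + S)^-1
    sigma2: float
    rss: float
    n: int
    edf_total: float
    edf_by_term: dict[str, float]
    aic: float
    deviance_explained: float
    r2_adj: float
    log_lambda: dict[str, float]
    column_names: list[str]
    slices: dict[str, slice]
    smooths: list
    factor_levels: dict[str, list]
    y_mean: float

    def parametric_table(self) -> pd.DataFrame:
        """Intercept and factor-level coefficients with SE, t and p."""
        idx = list(range(self.slices["__parametric__"].stop))
        est = self.beta[idx]
        se = np.sqrt(np.diag(self.cov)[idx])
        tval = est / se
        df_res = max(self.n - self.edf_total, 1.0)
        p = 2 * t_dist.sf(np.abs(tval), df_res)
        return pd.DataFrame(
            {
                "term": [self.column_names[i] for i in idx],
                "estimate": est,
                "std_error": se,
                "t_value": tval,
                "p_value": p,
            }
        )

    def smooth_table(self) -> pd.DataFrame:
        """Approximate Wald F tests for each smooth term."""
        rows = []
        df_res = max(self.n - self.edf_total, 1.0)
        for sm in self.smooths:
            sl = self.slices[sm.label]
            b = self.beta[sl]
            V = self.cov[sl, sl]
            edf = self.edf_by_term[sm.label]
            stat = float(b @ np.linalg.pinv(V, rcond=1e-10) @ b)
            fval = stat / max(edf, 1e-8)
            p = float(f_dist.sf(fval, max(edf, 1e-8), df_res))
            rows.append(
                {"term": sm.label, "edf": edf, "F": fval, "p_value": p}
            )
        return pd.DataFrame(rows)

    def smooth_curve(self, label: str, n_grid: int = 100) -> pd.DataFrame:
        """Centered partial-effect grid with pointwise 95% bands (1-D terms)."""
        sm = next(s for s in self.smooths if s.label == label)
        if len(sm.variables) != 1:
            raise ValidationError(f"{label} is not one-dimensional")
        grid = np.linspace(sm._lo, sm._hi, n_grid)
        Bg = sm.basis_at(grid)
        sl = self.slices[label]
        fit = Bg @ self.beta[sl]
        se = np.sqrt(np.einsum("ij,jk,ik->i", Bg, self.cov[sl, sl], Bg))
        return pd.DataFrame(
            {
                sm.var: grid,
                "estimate": fit,
                "lower_95": fit - 1.96 * se,
                "upper_95": fit + 1.96 * se,
            }
        )

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = _design_for_prediction(self, data)
        return X @ self.beta


def _factor_design(
    data: pd.DataFrame, factors: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list]]:
    cols, names, levels = [], [], {}
    for f in factors:
        vals = data[f]
        lv = sorted(pd.unique(vals))
        levels[f] = lv
        for level in lv[1:]:  # first (sorted) level is the reference
            cols.append((vals == level).to_numpy(dtype=float))
            names.append(f"{f}[{level}]")
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names, levels


def _design_for_prediction(fit: GamFit, data: pd.DataFrame) -> np.ndarray:
    n = len(data)
    blocks = [np.ones((n, 1))]
    for f, lv in fit.factor_levels.items():
        for level in lv[1:]:
            blocks.append((data[f] == level).to_numpy(dtype=float).reshape(-1, 1))
    for sm in fit.smooths:
        if len(sm.variables) == 1:
            blocks.append(sm.basis_at(data[sm.var].to_numpy(float)))
        else:
            blocks.append(
                sm.basis_at(
                    data[sm.var_x].to_numpy(float), data[sm.var_y].to_numpy(float)
                )
            )
    return np.hstack(blocks)


def fit_gaussian_gam(
    y,
    data: pd.DataFrame,
    smooths: list | None = None,
    factors: list[str] | None = None,
    log_lambda: dict[str, float] | None = None,
) -> GamFit:
    """Fit a Gaussian/identity additive model; REML selects the penalties.

    Parameters
    ----------
    y : array or column name in ``data``
    smooths : list of :class:`SmoothTerm` / :class:`TensorSmooth`
    factors : categorical column names; first sorted level is the baseline
    log_lambda : optional fixed log smoothing parameters per smooth label,
        bypassing REML (used for oracle checks and degenerate-limit tests)

    Returns a :class:`GamFit`.  The fit is deterministic given the data and
    specification: the REML search starts from log-lambda = 0 for every term
    and uses a bounded Nelder-Mead simplex.
    """
    smooths = list(smooths or [])
    factors = list(factors or [])
    if isinstance(y, str):
        y = data[y]
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n != len(data):
        raise ValidationError("response and data lengths differ")
    for sm in smooths:
        for v in sm.variables:
            if v not in data.columns:
                raise ConfigurationError(f"smooth variable {v!r} not in data")
    for f in factors:
        if f not in data.columns:
            raise ConfigurationError(f"factor {f!r} not in data")

    Xf, f_names, f_levels = _factor_design(data, factors)
    blocks = [np.ones((n, 1)), Xf]
    names = ["(Intercept)"] + f_names
    penalties: list[tuple[slice, np.ndarray, float]] = []  # (cols, S, rank)
    slices: dict[str, slice] = {}
    col = 1 + Xf.shape[1]
    slices["__parametric__"] = slice(0, col)
    for sm in smooths:
        Bc, Sc = sm.build(data)
        lr_req = None if log_lambda is None else log_lambda.get(sm.label, 0.0)
        if lr_req is not None and math.isinf(lr_req) and lr_req > 0:
            # exact infinite-penalty limit: restrict the term to the penalty
            # null space (e.g. the linear trend for a second-difference
            # penalty), which turns it into an unpenalized parametric block
            evals, evecs = np.linalg.eigh(Sc)
            null = evecs[:, evals <= _EIG_TOL * max(evals.max(), 1.0)]
            sm._Z = sm._Z @ null  # keep prediction consistent
            Bc = Bc @ null
            Sc = np.zeros((Bc.shape[1], Bc.shape[1]))
        sl = slice(col, col + Bc.shape[1])
        slices[sm.label] = sl
        blocks.append(Bc)
        names.extend(f"{sm.label}.{i}" for i in range(Bc.shape[1]))
        evals = np.linalg.eigvalsh(Sc)
        rank = int((evals > _EIG_TOL * evals.max()).sum())
        penalties.append((sl, Sc, rank))
        col += Bc.shape[1]
    X = np.hstack(blocks)
    p = X.shape[1]

    # Unpenalized (parametric) columns must be identifiable on their own;
    # penalized spline blocks may contain unsupported basis columns (no data
    # in a knot span) -- the roughness penalty regularizes those, exactly as
    # in any penalized-spline fit, so they are checked jointly with the
    # penalty below.
    n_par = slices["__parametric__"].stop
    r_par = np.linalg.matrix_rank(X[:, :n_par])
    if r_par < n_par:
        raise ValidationError(
            f"rank-deficient parametric design ({r_par} < {n_par}); aliased "
            f"factor levels among {names[:n_par]}"
        )

    XtX = X.T @ X
    Xty = X.T @ yv
    yty = float(yv @ yv)

    def assemble(rho: np.ndarray) -> np.ndarray:
        A = XtX.copy()
        for (sl, S, _), lr in zip(penalties, rho):
            A[sl, sl] += math.exp(lr) * S
        return A

    total_rank = sum(rk for _, _, rk in penalties)
    M = p - total_rank  # unpenalized directions

    def reml(rho: np.ndarray) -> float:
        rho = np.clip(rho, -25.0, 30.0)
        A = assemble(rho)
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return 1e12
        beta = np.linalg.solve(A, Xty)
        rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
        pen = 0.0
        for (sl, S, _), lr in zip(penalties, rho):
            pen += math.exp(lr) * float(beta[sl] @ S @ beta[sl])
        rss_p = max(rss + pen, 1e-300)
        logdet_A = 2.0 * float(np.log(np.diag(L)).sum())
        logdet_S = sum(rk * lr for (_, _, rk), lr in zip(penalties, rho))
        return (n - M) * math.log(rss_p) + logdet_A - logdet_S

    if penalties:
        try:
            np.linalg.cholesky(assemble(np.zeros(len(penalties))))
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "design not identifiable even under penalization; aliased or "
                f"collinear terms among {names}"
            ) from exc
        if log_lambda is not None:
            rho_hat = np.array(
                [
                    0.0  # the inf case was absorbed into the basis above
                    if math.isinf(log_lambda.get(sm.label, 0.0))
                    else log_lambda.get(sm.label, 0.0)
                    for sm in smooths
                ],
                dtype=float,
            )
        else:
            res = minimize(
                reml,
                x0=np.zeros(len(penalties)),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000},
            )
            rho_hat = np.clip(res.x, -25.0, 30.0)
    else:
        rho_hat = np.empty(0)

    A = assemble(rho_hat)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ Xty
    resid = yv - X @ beta
    rss = float(resid @ resid)
    F_inf = Ainv @ XtX  # influence of the data on each coefficient
    edf_total = float(np.trace(F_inf))
    edf_by_term = {}
    for sm, (sl, _, _) in zip(smooths, penalties):
        edf_by_term[sm.label] = float(np.trace(F_inf[sl, sl]))
    sigma2 = rss / max(n - edf_total, 1e-8)
    cov = sigma2 * Ainv

    sigma2_ml = rss / n
    loglik = -0.5 * n * (math.log(2 * math.pi * max(sigma2_ml, 1e-300)) + 1.0)
    aic = -2.0 * loglik + 2.0 * (edf_total + 1.0)

    tss = float(((yv - yv.mean()) ** 2).sum())
    dev_expl = 0.0 if tss == 0 else 1.0 - rss / tss
    r2_adj = (
        0.0
        if tss == 0
        else 1.0 - (rss / max(n - edf_total, 1e-8)) / (tss / (n - 1))
    )

    return GamFit(
        beta=beta,
        cov=cov,
        sigma2=sigma2,
        rss=rss,
        n=n,
        edf_total=edf_total,
        edf_by_term=edf_by_term,
        aic=aic,
        deviance_explained=dev_expl,
        r2_adj=r2_adj,
        log_lambda={
            sm.label: float(lr) for sm, lr in zip(smooths, rho_hat)
        },
        column_names=names,
        slices=slices,
        smooths=smooths,
        factor_levels=f_levels,
        y_mean=float(yv.mean()),
    )
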