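"""Tonic (background) connectivity via graphical lasso with BIC selection.

Task-evoked variance is first removed from every node's series by OLS on
the task regressors and confounds; the residuals' sparse precision matrix
is then estimated by L1-penalised Gaussian maximum likelihood over a
penalty grid, with the penalty chosen per run and per subject by
minimising the Bayesian Information Criterion.  Run precisions are
averaged and rectified into the tonic connectivity matrix.

Residuals are variance-standardised per node before the covariance is
formed, so a given penalty is comparable across runs and subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_glasso
from sklearn.exceptions import ConvergenceWarning

from .design import DesignMatrix
from .phasic import ConnectivityMatrix, _check_rank, average_runs, rectify, symmetrize

#: default penalty grid: 25 log-spaced values
DEFAULT_LAMBDA_GRID = np.logspace(np.log10(0.01), np.log10(1.0), 25)

#: |theta_ij| above this counts as a nonzero edge (support)
SUPPORT_TOL = 1e-8

#: convergence: max absolute parameter change between refinement steps
GLASSO_TOL = 1e-5
#: coordinate-descent sweeps for the warm solve; the proximal refinement
#: then iterates to the convergence criterion above
GLASSO_MAX_ITER = 20
_POLISH_MAX_ITER = 2000


@dataclass(frozen=True)
class GlassoFit:
    precision: np.ndarray
    lam: float
    loglik: float
    bic: float
    n_obs: int

    @property
    def support(self) -> np.ndarray:
        """Boolean strictly-upper-triangle edge support."""
        n = self.precision.shape[0]
        iu = np.triu_indices(n, 1)
        return np.abs(self.precision[iu]) > SUPPORT_TOL


def residualize(ts_run: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """OLS residuals of every node on [intercept, safe, look, confounds]."""
    ts_run = np.asarray(ts_run, dtype=float)
    n, T = ts_run.shape
    if T != design.n_timepoints:
        raise ValueError("time dimension does not match design")
    X = np.column_stack([np.ones(T), design.task_matrix(),
                         design.confound_matrix()])
    _check_rank(X, ["intercept", *design.column_labels])
    beta, *_ = np.linalg.lstsq(X, ts_run.T, rcond=None)
    return ts_run - (X @ beta).T


def gaussian_loglik(precision: np.ndarray, S: np.ndarray, n_obs: int) -> float:
    """Unpenalised Gaussian log-likelihood at a given precision matrix."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return 0.5 * n_obs * (logdet - np.trace(S @ precision)
                          - p * np.log(2.0 * np.pi))


def glasso_bic(fit_precision: np.ndarray, S: np.ndarray, n_obs: int) -> float:
    """BIC = -2*loglik + k*ln(n); k = upper-triangle support + diagonal."""
    p = S.shape[0]
    iu = np.triu_indices(p, 1)
    k = int((np.abs(fit_precision[iu]) > SUPPORT_TOL).sum()) + p
    return -2.0 * gaussian_loglik(fit_precision, S, n_obs) + k * np.log(n_obs)


def _penalized_objective(T: np.ndarray, S: np.ndarray, lam: float) -> float:
    off = ~np.eye(S.shape[0], dtype=bool)
    sign, ld = np.linalg.slogdet(T)
    if sign <= 0:
        return np.inf
    return -ld + np.trace(S @ T) + lam * np.abs(T[off]).sum()


def _prox_refine(S: np.ndarray, lam: float, T0: np.ndarray,
                 tol: float, max_iter: int) -> np.ndarray:
    """Monotone proximal-gradient refinement of a glasso solution.

    Declares convergence when the max absolute parameter change in one
    step falls below ``tol``; raises after ``max_iter`` steps otherwise.
    """
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    T = T0.copy()
    fo = _penalized_objective(T, S, lam)
    step = 1.0 / np.linalg.eigvalsh(np.linalg.inv(T))[-1] ** 2
    for it in range(max_iter):
        G = S - np.linalg.inv(T)
        s = step
        while True:
            Tn = T - s * G
            Tn[off] = np.sign(Tn[off]) * np.maximum(np.abs(Tn[off]) - s * lam,
                                                    0.0)
            Tn = (Tn + Tn.T) / 2.0
            fn = _penalized_objective(Tn, S, lam)
            if fn <= fo:
                break
            s /= 2.0
            if s < 1e-15:
                return T  # at a numerical fixed point
        delta = float(np.max(np.abs(Tn - T)))
        T, fo = Tn, fn
        if delta < tol:
            return T
    raise RuntimeError(
        f"did not converge within {max_iter} refinement steps "
        f"(last max parameter change {delta:.2e} >= tol {tol:g})")


def graphical_lasso_fit(S: np.ndarray, lam: float, n_obs: int = 0,
                        tol: float = GLASSO_TOL) -> GlassoFit:
    """Maximise log det(T) - tr(S T) - lam * sum_{i!=j} |T_ij|.

    The diagonal is unpenalised.  A coordinate-descent solve is refined by
    proximal-gradient steps until the max parameter change drops below
    ``tol``.  ``n_obs`` is carried through for BIC computation; pass the
    number of timepoints the covariance came from.
    """
    S = np.asarray(S, dtype=float)
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be a symmetric square matrix")
    if np.any(np.diag(S) <= 0):
        raise ValueError("S must have a strictly positive diagonal")
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    if lam == 0.0:
        prec = np.linalg.inv(S)
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, prec = _sk_glasso(S, alpha=lam, tol=GLASSO_TOL,
                                     max_iter=GLASSO_MAX_ITER)
            prec = _prox_refine(S, lam, (prec + prec.T) / 2.0, tol,
                                _POLISH_MAX_ITER)
        except (FloatingPointError, RuntimeError) as exc:
            raise RuntimeError(
                f"graphical lasso did not converge at lambda={lam:g}: "
                f"{exc}") from exc
    prec = (prec + prec.T) / 2.0
    # clean numerically-tiny off-diagonals so support counting is stable
    off = ~np.eye(S.shape[0], dtype=bool)
    prec[off & (np.abs(prec) <= SUPPORT_TOL)] = 0.0
    n = n_obs or S.shape[0]
    ll = gaussian_loglik(prec, S, n)
    return GlassoFit(precision=prec, lam=float(lam), loglik=ll,
                     bic=glasso_bic(prec, S, n), n_obs=n)


def select_lambda_bic(
    residuals: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    standardize: bool = True,
) -> GlassoFit:
    """Fit the penalty grid on the residual covariance, return the BIC
    minimiser (ties go to the smaller penalty)."""
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("lambda grid must be non-empty and strictly increasing")
    R = np.asarray(residuals, dtype=float)
    p, T = R.shape
    Rc = R - R.mean(axis=1, keepdims=True)
    if standardize:
        sd = Rc.std(axis=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance residual series")
        Rc = Rc / sd[:, None]
    S = Rc @ Rc.T / T
    best: GlassoFit | None = None
    errors = []
    for lam in grid:
        try:
            fit = graphical_lasso_fit(S, lam, n_obs=T)
        except RuntimeError as exc:
            errors.append(str(exc))
            continue
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise RuntimeError("all graphical-lasso fits failed: "
                           + "; ".join(errors))
    return best


def estimate_tonic_subject(
    ts_runs: np.ndarray,
    designs: list[DesignMatrix],
    node_labels: tuple[str, ...],
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    standardize: bool = True,
) -> ConnectivityMatrix:
    """Per-run residualize -> BIC-selected glasso precision; run-average the
    zero-diagonal precisions, then take absolute values (tag ``tonic``)."""
    if len(ts_runs) < 1:
        raise ValueError("need at least one run")
    mats = []
    for r, (run, dm) in enumerate(zip(ts_runs, designs)):
        try:
            resid = residualize(run, dm)
            fit = select_lambda_bic(resid, lambda_grid, standardize)
        except Exception as exc:
            raise RuntimeError(
                f"tonic estimation failed in run {r + 1}: {exc}") from exc
        mats.append(symmetrize(fit.precision, "tonic", node_labels))
    return rectify(average_runs(mats))
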