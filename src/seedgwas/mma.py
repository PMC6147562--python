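"""EMMAX-style mixed-model association.

The defining approximation: variance components (genetic sigma_g^2 against a
kinship matrix K, plus residual sigma_e^2) are estimated ONCE per
trait/treatment under the null model by REML, and every marker is then tested
by generalized least squares with the covariance V = sigma_g^2 K +
sigma_e^2 I held fixed. Tests are two-sided F-tests on the dosage
coefficient; reported effects are per copy of the MAJOR allele (the negated
minor-allele coefficient), matching the field's reporting convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from ._util import UserInputError, logger
from .panel import GenotypePanel, KinshipMatrix, StructureModel
from .phenostats import TraitMatrix

__all__ = ["VarianceComponents", "estimate_vc", "score_snp", "gwa_scan", "gwa_scan_all"]

_LOG10_DELTA_RANGE = (-5.0, 5.0)
_GRID_POINTS = 100


@dataclasses.dataclass
class VarianceComponents:
    """REML variance components of the null model y = X0 b + g + e.

    delta = sigma_e^2 / sigma_g^2; ``boundary`` flags a flat or edge REML
    profile (sigma_g^2 effectively 0, or residual variance effectively 0).
    """

    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    boundary: bool = False


def _reml_profile(eta2: np.ndarray, xi: np.ndarray, nq: int):
    """Restricted log-likelihood as a function of delta (= sigma_e^2/sigma_g^2)."""

    def rll(delta: float) -> float:
        d = xi + delta
        quad = np.sum(eta2 / d)
        return 0.5 * (
            nq * np.log(nq / (2.0 * np.pi))
            - nq
            - nq * np.log(quad)
            - np.sum(np.log(d))
        )

    return rll


def estimate_vc(y: np.ndarray, X0: np.ndarray, K: np.ndarray) -> VarianceComponents:
    """REML profile over delta via eigendecomposition of the null-projected kinship.

    The restricted likelihood is profiled on a 100-point grid over
    log10(delta) in [-5, 5] and refined locally to |d log10 delta| < 1e-6.
    A flat profile (e.g. K = I, where relatedness carries no signal) is
    returned with the boundary flag and sigma_g^2 = 0.
    """
    y = np.asarray(y, dtype=float)
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    K = np.asarray(K, dtype=float)
    n = len(y)
    q = X0.shape[1]
    if X0.shape[0] != n or K.shape != (n, n):
        raise UserInputError("estimate_vc: dimension mismatch")
    w_check = np.linalg.eigvalsh(K)
    if w_check.min() < -1e-8:
        raise UserInputError(f"kinship not PSD (min eigenvalue {w_check.min():.3g})")

    # project out the null covariates, keep the n-q informative directions
    Q0, _ = np.linalg.qr(X0)
    S = np.eye(n) - Q0 @ Q0.T
    M = S @ K @ S
    M = (M + M.T) / 2.0
    w, U = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    nq = n - q
    xi = np.clip(w[order][:nq], 0.0, None)
    eta = U[:, order][:, :nq].T @ y
    eta2 = eta**2

    rll = _reml_profile(eta2, xi, nq)
    grid = np.linspace(*_LOG10_DELTA_RANGE, _GRID_POINTS)
    vals = np.array([rll(10.0**g) for g in grid])
    span = vals.max() - vals.min()
    if span < 1e-8 * max(1.0, abs(vals.max())):
        # flat profile: no identifiable genetic variance
        sigma_e2 = float(eta2.sum() / nq)
        logger.info("estimate_vc: flat REML profile; sigma_g^2 -> 0 boundary")
        return VarianceComponents(0.0, sigma_e2, np.inf, float(vals[0]), boundary=True)
    best = int(np.argmax(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = scipy.optimize.minimize_scalar(
        lambda g: -rll(10.0**g), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    log_delta = float(res.x)
    delta = 10.0**log_delta
    sigma_g2 = float(np.sum(eta2 / (xi + delta)) / nq)
    sigma_e2 = delta * sigma_g2
    boundary = best in (0, len(grid) - 1)
    if boundary:
        logger.info("estimate_vc: REML optimum at grid edge (log10 delta=%.1f)", grid[best])
    return VarianceComponents(sigma_g2, sigma_e2, delta, float(rll(delta)), boundary=boundary)


def _rotation(vc: VarianceComponents, K: np.ndarray):
    """Eigen-rotation and per-direction GLS weights for V = sg^2 K + se^2 I."""
    n = K.shape[0]
    if vc.boundary and not np.isfinite(vc.delta):
        return np.eye(n), np.full(n, 1.0 / vc.sigma_e2)
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return U, 1.0 / (vc.sigma_g2 * w + vc.sigma_e2)


def _wls_last_coef(Xw: np.ndarray, yw: np.ndarray):
    """Weighted LS estimate, SE and F p-value for the LAST column of X."""
    n, p = Xw.shape
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    try:
        # Schur complement of the last coefficient
        A = XtX[:-1, :-1]
        a = XtX[:-1, -1]
        c = XtX[-1, -1]
        Ainv_a = np.linalg.solve(A, a)
        denom = c - a @ Ainv_a
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan
    if denom <= 1e-10 * max(c, 1.0):
        return np.nan, np.nan, np.nan
    Ainv_Xty = np.linalg.solve(A, Xty[:-1])
    beta_x = (Xty[-1] - a @ Ainv_Xty) / denom
    beta0 = Ainv_Xty - Ainv_a * beta_x
    rss = yw @ yw - Xty[:-1] @ beta0 - Xty[-1] * beta_x
    dfden = n - p
    if dfden <= 0 or rss <= 0:
        return beta_x, np.nan, np.nan
    sigma2 = rss / dfden
    F = beta_x**2 * denom / sigma2
    p_value = float(scipy.stats.f.sf(F, 1, dfden))
    return float(beta_x), float(np.sqrt(sigma2 / denom)), p_value


def score_snp(
    y: np.ndarray,
    x: np.ndarray,
    X0: np.ndarray,
    vc: VarianceComponents,
    K: np.ndarray,
) -> dict:
    """GLS test of one dosage column with variance components held fixed.

    Missing dosages are mean-imputed; the test is a two-sided F(1, n - q - 1)
    on the minor-allele coefficient, and ``beta_major`` is its negation. A
    dosage collinear with the covariates yields a missing p-value.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float).copy()
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    if np.isnan(x).any():
        x[np.isnan(x)] = np.nanmean(x)
    U, wts = _rotation(vc, np.asarray(K, dtype=float))
    sw = np.sqrt(wts)
    yw = (U.T @ y) * sw
    Xw = (U.T @ np.column_stack([X0, x])) * sw[:, None]
    beta_minor, se, p = _wls_last_coef(Xw, yw)
    if np.isnan(p):
        logger.info("score_snp: dosage collinear with covariates; p-value missing")
    return {
        "beta_minor": beta_minor,
        "beta_major": -beta_minor if np.isfinite(beta_minor) else np.nan,
        "se": se,
        "p_value": p,
        "n_used": len(y),
    }


def _scan_matrix(
    y: np.ndarray, G: np.ndarray, X0: np.ndarray, vc: VarianceComponents, K: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-marker GLS over a dosage matrix (missing mean-imputed).

    Returns (beta_minor, p_value) arrays. Algebra: in the eigen-rotated,
    weighted basis the marker coefficient is the Schur complement of the
    covariate block, which vectorizes over markers as matrix products.
    """
    n, m = G.shape
    q = X0.shape[1]
    G = G.copy()
    col_mean = np.nanmean(G, axis=0)
    r, c = np.nonzero(np.isnan(G))
    G[r, c] = col_mean[c]

    U, wts = _rotation(vc, K)
    sw = np.sqrt(wts)
    yw = (U.T @ y) * sw
    X0w = (U.T @ X0) * sw[:, None]
    Gw = (U.T @ G) * sw[:, None]

    A = X0w.T @ X0w                       # q x q
    Ainv = np.linalg.inv(A)
    X0ty = X0w.T @ yw                     # q
    a_all = X0w.T @ Gw                    # q x m
    c_all = np.einsum("ij,ij->j", Gw, Gw)  # m
    d_all = Gw.T @ yw                     # m

    Ainv_a = Ainv @ a_all                 # q x m
    denom = c_all - np.einsum("qm,qm->m", a_all, Ainv_a)
    Ainv_X0ty = Ainv @ X0ty
    beta_x = np.where(denom > 0, (d_all - a_all.T @ Ainv_X0ty) / np.where(denom > 0, denom, 1.0), np.nan)

    # residual sum of squares per marker
    beta0 = Ainv_X0ty[:, None] - Ainv_a * beta_x[None, :]   # q x m
    rss = yw @ yw - X0ty @ beta0 - d_all * beta_x
    dfden = n - q - 1
    sigma2 = rss / dfden
    with np.errstate(invalid="ignore", divide="ignore"):
        F = beta_x**2 * denom / sigma2
        p = scipy.stats.f.sf(F, 1, dfden)
    bad = (denom <= 1e-10 * np.maximum(c_all, 1.0)) | ~np.isfinite(F)
    beta_x = np.where(bad, np.nan, beta_x)
    p = np.where(bad, np.nan, p)
    if bad.any():
        logger.info("scan: %d markers collinear with covariates (p-value missing)", int(bad.sum()))
    return beta_x, p


def gwa_scan(
    tm: TraitMatrix,
    panel: GenotypePanel,
    K: KinshipMatrix,
    Q: StructureModel | np.ndarray | None,
    trait: str,
    treatment: str,
    n_components: int = 4,
    min_lines: int = 30,
) -> pd.DataFrame:
    """Genome-ordered association scan of one trait in one treatment.

    Line sets are reconciled by intersection between the panel and the
    phenotype vector (logged); fewer than ``min_lines`` overlapping lines is
    a hard error. Output is a Manhattan-ready table with one row per filtered
    marker: chrom, pos, beta_major, p_value, -log10 P.
    """
    y_ser = tm.vector(trait, treatment)
    if y_ser.empty:
        raise UserInputError(f"no phenotype values for {trait}/{treatment}")
    lines = [l for l in panel.line_ids if l in set(y_ser.index)]
    dropped = panel.n_lines - len(lines) + (len(y_ser) - len(lines))
    if dropped:
        logger.info("gwa_scan(%s/%s): %d lines outside the panel/phenotype intersection",
                    trait, treatment, dropped)
    if len(lines) < min_lines:
        raise UserInputError(
            f"only {len(lines)} overlapping lines for {trait}/{treatment}; "
            f"need >= {min_lines}"
        )
    sub = panel.take_lines(lines)
    y = y_ser.loc[lines].to_numpy()
    Ksub = K.subset(lines).values
    if Q is None:
        X0 = np.ones((len(lines), 1))
    elif isinstance(Q, StructureModel):
        X0 = np.column_stack([np.ones(len(lines)), Q.covariates(lines, n_components)])
    else:
        # plain array: rows aligned with panel.line_ids
        Qarr = np.atleast_2d(np.asarray(Q, dtype=float))
        if Qarr.shape[0] != panel.n_lines:
            raise UserInputError("Q array rows must align with panel lines")
        pos = {l: i for i, l in enumerate(panel.line_ids)}
        Qsub = Qarr[[pos[l] for l in lines], :n_components]
        X0 = np.column_stack([np.ones(len(lines)), Qsub])
    vc = estimate_vc(y, X0, Ksub)
    beta_minor, p = _scan_matrix(y, sub.dosage, X0, vc, Ksub)
    out = pd.DataFrame(
        {
            "marker": sub.markers["id"].to_numpy(),
            "chrom": sub.markers["chrom"].to_numpy(),
            "pos": sub.markers["pos"].to_numpy(),
            "trait": trait,
            "treatment": treatment,
            "beta_major": -beta_minor,
            "beta_minor": beta_minor,
            "p_value": p,
            "n_used": len(lines),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["neglog10_p"] = -np.log10(out["p_value"])
    out.attrs["variance_components"] = vc
    return out


def gwa_scan_all(
    tm: TraitMatrix,
    panel: GenotypePanel,
    K: KinshipMatrix,
    Q: StructureModel | np.ndarray | None,
    n_components: int = 4,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Scan every trait x treatment combination in the trait matrix."""
    out = {}
    for trait in tm.traits:
        for treatment in tm.treatments:
            out[(trait, treatment)] = gwa_scan(
                tm, panel, K, Q, trait, treatment, n_components=n_components
            )
    return out
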