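"""Animal-model machinery: design matrices, MME solving and REML.

The model is y = Xb + Zu + e with fixed effects b (contemporary-group
class + linear age covariate), additive genetic effects u ~ N(0, K sigma_u2)
for a relationship matrix K (pedigree A or single-step H), and
e ~ N(0, I sigma_e2).

REML is computed after a one-off eigendecomposition of the record-level
kinship M = Z K Z': in the rotated basis every variance structure in the
model is diagonal, so each average-information (AI) iteration costs O(n p^2).
The bivariate model uses the same rotation, where records decouple into
independent 2x2 blocks G0*lambda_i + R0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .pedigree import Pedigree, nrm


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


# ----------------------------------------------------------------------
# design matrices
# ----------------------------------------------------------------------

def build_design(
    phenotypes: pd.DataFrame,
    cg_col: str = "cg",
    age_col: str = "age",
    animal_col: str = "animal_id",
    pedigree: Pedigree | None = None,
):
    """Fixed-effect design X and record-to-animal map.

    X holds one indicator column per contemporary-group level plus the
    centered age covariate (full rank: the group indicators span the
    intercept).  Returns ``(X, column_names, rec_idx)`` where ``rec_idx``
    maps records to pedigree positions (None when no pedigree is given).
    """
    cg = phenotypes[cg_col].astype(str).to_numpy()
    levels, codes = np.unique(cg, return_inverse=True)
    n = len(phenotypes)
    if len(levels) >= n:
        warnings.warn("every record is its own contemporary group: model saturated")
    X = np.zeros((n, len(levels) + 1))
    X[np.arange(n), codes] = 1.0
    age = phenotypes[age_col].to_numpy(dtype=float)
    X[:, -1] = age - age.mean()
    names = [f"{cg_col}={lv}" for lv in levels] + [age_col]
    rec_idx = None
    if pedigree is not None:
        rec_idx = pedigree.indices(phenotypes[animal_col])
    return X, names, rec_idx


def design_z(rec_idx: np.ndarray, n_animals: int) -> np.ndarray:
    """Dense incidence matrix mapping records to animal equations."""
    Z = np.zeros((len(rec_idx), n_animals))
    Z[np.arange(len(rec_idx)), rec_idx] = 1.0
    return Z


# ----------------------------------------------------------------------
# mixed model equations
# ----------------------------------------------------------------------

@dataclass
class MmeSolution:
    """Solution of Henderson's mixed-model equations."""

    b: np.ndarray
    u: np.ndarray
    coeff_inverse: np.ndarray | None = None
    column_names: list[str] = field(default_factory=list)

    @property
    def n_fixed(self) -> int:
        return self.b.size


def solve_mme(
    X: np.ndarray,
    Z: np.ndarray,
    K_inv: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
    y: np.ndarray,
    compute_inverse: bool = False,
    column_names: list[str] | None = None,
) -> MmeSolution:
    """Solve [X'X X'Z; Z'X Z'Z + K^-1 lam][b;u] = [X'y; Z'y], lam = se2/su2.

    Animals without records receive predictions through the kinship.
    Raises on a rank-deficient fixed block, naming confounded columns.
    """
    if sigma_u2 <= 0 or sigma_e2 <= 0:
        raise ValueError("variance components must be positive")
    p = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        dropped = piv[rank:]
        names = column_names or [f"col{j}" for j in range(p)]
        raise np.linalg.LinAlgError(
            "fixed-effect design is rank deficient; confounded columns: "
            + ", ".join(names[j] for j in dropped)
        )
    lam = sigma_e2 / sigma_u2
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + K_inv * lam]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    cf = linalg.cho_factor(C, lower=True)
    sol = linalg.cho_solve(cf, rhs)
    resid = C @ sol - rhs
    assert np.linalg.norm(resid) < 1e-6 * max(np.linalg.norm(rhs), 1.0), "MME solve inaccurate"
    Cinv = linalg.cho_solve(cf, np.eye(C.shape[0])) if compute_inverse else None
    return MmeSolution(b=sol[:p], u=sol[p:], coeff_inverse=Cinv, column_names=column_names or [])


# ----------------------------------------------------------------------
# REML in the eigenbasis of M = Z K Z'
# ----------------------------------------------------------------------

class _Rotation:
    """Eigenrotation of the record-level kinship M = Z K Z'."""

    def __init__(self, M: np.ndarray, X: np.ndarray, Y: np.ndarray):
        lam, U = np.linalg.eigh(M)
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        self.Xt = U.T @ X
        self.Yt = U.T @ Y if Y.ndim > 1 else U.T @ Y[:, None]


def _single_loglik(theta, rot: _Rotation):
    """REML log-likelihood, score and AI matrix for theta = (su2, se2)."""
    su2, se2 = theta
    lam, Xt = rot.lam, rot.Xt
    y = rot.Yt[:, 0]
    n, p = Xt.shape
    v = su2 * lam + se2
    vinv = 1.0 / v
    Xv = Xt * vinv[:, None]
    C = Xt.T @ Xv
    cf = linalg.cho_factor(C, lower=True)
    xvy = Xv.T @ y
    b = linalg.cho_solve(cf, xvy)
    r = (y - Xt @ b) * vinv  # r = P y
    ypy = float(y @ r)
    logdet_v = float(np.sum(np.log(v)))
    logdet_c = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ll = -0.5 * (logdet_v + logdet_c + ypy)

    # score and AI for dV/dsu2 = diag(lam), dV/dse2 = I
    dots = (lam, np.ones(n))
    score = np.empty(2)
    work = []
    for k, dk in enumerate(dots):
        Tk = Xv.T @ (Xv * dk[:, None])
        tr_p_dk = float(np.sum(dk * vinv)) - float(np.trace(linalg.cho_solve(cf, Tk)))
        score[k] = -0.5 * (tr_p_dk - float(r @ (dk * r)))
        work.append(dk * r)

    def apply_p(w):
        return w * vinv - Xv @ linalg.cho_solve(cf, Xv.T @ w)

    AI = np.empty((2, 2))
    pw = [apply_p(w) for w in work]
    for k in range(2):
        for m in range(k, 2):
            AI[k, m] = AI[m, k] = 0.5 * float(work[k] @ pw[m])
    return ll, score, AI, b, r, cf


@dataclass
class VarianceComponents:
    """Single-trait variance components with standard errors."""

    sigma_u2: float
    sigma_e2: float
    h2: float
    se_sigma_u2: float
    se_sigma_e2: float
    se_h2: float
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)


def _ai_reml(rot: _Rotation, start=None, maxiter: int = 200, tol: float = 1e-8):
    """AI-REML with damped EM-style fallback (non-decreasing log-likelihood)."""
    y = rot.Yt[:, 0]
    vary = float(np.var(y, ddof=1))
    floor = 1e-8 * vary
    theta = np.array(start) if start is not None else np.array([0.5 * vary, 0.5 * vary])
    ll, score, AI, *_ = _single_loglik(theta, rot)
    trace = [(theta.copy(), ll)]
    n = y.size
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = None
        new = None
        if step is not None:
            cands = [np.maximum(theta + step, floor)]
            neg = theta + step < floor
            if neg.any():
                # scale the whole AI step so the boundary component lands on it
                t = np.min((theta[neg] - floor) / np.maximum(-step[neg], 1e-300))
                cands.append(np.maximum(theta + min(max(t, 0.0), 1.0) * step, floor))
            best_ll = -np.inf
            for cand in cands:
                ll_new = _single_loglik(cand, rot)[0]
                if np.isfinite(ll_new) and ll_new >= max(ll - 1e-12, best_ll):
                    new, ll_cand, best_ll = cand, ll_new, ll_new
        if new is None:
            # EM-style step: positive diagonal scaling of the score is an
            # ascent direction; halve until the likelihood does not decrease
            step = 2.0 * theta**2 * score / n
            for _ in range(60):
                cand = np.maximum(theta + step, floor)
                ll_new = _single_loglik(cand, rot)[0]
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    new, ll_cand = cand, ll_new
                    break
                step *= 0.5
            else:
                raise ConvergenceError("REML line search failed", trace)
        dll = ll_cand - ll
        theta, ll = new, ll_cand
        ll, score, AI, b, r, cf = _single_loglik(theta, rot)
        trace.append((theta.copy(), ll))
        if abs(dll) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"REML did not converge in {maxiter} iterations", trace)
    return theta, ll, score, AI, trace, it


def reml_single(
    y: np.ndarray,
    X: np.ndarray,
    M: np.ndarray,
    start=None,
    maxiter: int = 200,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Single-trait AI-REML given the record-level kinship M = Z K Z'.

    Standard errors come from the inverse AI matrix at convergence; the
    heritability SE uses the delta method.
    """
    y = np.asarray(y, dtype=float)
    rot = _Rotation(np.asarray(M, dtype=float), np.asarray(X, dtype=float), y)
    theta, ll, score, AI, trace, it = _ai_reml(rot, start=start, maxiter=maxiter, tol=tol)
    su2, se2 = theta
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    tot = su2 + se2
    grad = np.array([se2, -su2]) / tot**2
    var_h2 = float(grad @ cov @ grad)
    return VarianceComponents(
        sigma_u2=float(su2),
        sigma_e2=float(se2),
        h2=float(su2 / tot),
        se_sigma_u2=float(np.sqrt(max(cov[0, 0], 0.0))),
        se_sigma_e2=float(np.sqrt(max(cov[1, 1], 0.0))),
        se_h2=float(np.sqrt(max(var_h2, 0.0))),
        loglik=float(ll),
        converged=True,
        n_iter=it,
        trace=trace,
    )


def reml_loglik_dense(y, X, V):
    """Brute-force REML log-likelihood from a dense covariance V (oracle)."""
    y = np.asarray(y, dtype=float)
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    b = np.linalg.solve(XVX, X.T @ Vi @ y)
    r = y - X @ b
    sign, logdet_v = np.linalg.slogdet(V)
    sign2, logdet_c = np.linalg.slogdet(XVX)
    return -0.5 * (logdet_v + logdet_c + float(r @ Vi @ r))


# ----------------------------------------------------------------------
# model / results objects
# ----------------------------------------------------------------------

class AnimalModel:
    """Single-trait animal model fitted by REML.

    Parameters
    ----------
    y : array, phenotypes (one record per animal)
    X : array, fixed-effect design (see :func:`build_design`)
    kinship : array
        Relationship matrix over all pedigree animals (A or H).
    rec_idx : array
        Pedigree position of each record's animal.
    """

    def __init__(self, y, X, kinship, rec_idx, animal_ids=None, column_names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.kinship = np.asarray(kinship, dtype=float)
        self.rec_idx = np.asarray(rec_idx, dtype=np.int64)
        self.animal_ids = animal_ids
        self.column_names = column_names or []
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise np.linalg.LinAlgError("fixed-effect design is rank deficient")

    @classmethod
    def from_dataframe(
        cls,
        phenotypes: pd.DataFrame,
        trait: str,
        pedigree: Pedigree,
        kinship: np.ndarray | None = None,
        cg_col: str = "cg",
        age_col: str = "age",
        animal_col: str = "animal_id",
    ) -> "AnimalModel":
        """Build from a phenotype table; kinship defaults to the pedigree A."""
        data = phenotypes[np.isfinite(phenotypes[trait].to_numpy(dtype=float))]
        X, names, rec_idx = build_design(data, cg_col, age_col, animal_col, pedigree)
        K = kinship if kinship is not None else nrm(pedigree).matrix
        return cls(
            data[trait].to_numpy(dtype=float), X, K, rec_idx,
            animal_ids=list(pedigree.ids), column_names=names,
        )

    def fit(self, start=None, maxiter: int = 200, tol: float = 1e-8) -> "AnimalModelResults":
        M = self.kinship[np.ix_(self.rec_idx, self.rec_idx)]
        vc = reml_single(self.y, self.X, M, start=start, maxiter=maxiter, tol=tol)
        # GLS fixed effects and BLUP at the converged components
        rot = _Rotation(M, self.X, self.y)
        _, _, _, b, r, _ = _single_loglik((vc.sigma_u2, vc.sigma_e2), rot)
        py = rot.U @ r  # P y back in record space
        zpy = np.zeros(self.kinship.shape[0])
        np.add.at(zpy, self.rec_idx, py)
        u = vc.sigma_u2 * (self.kinship @ zpy)
        return AnimalModelResults(model=self, vc=vc, b=b, u=u)


@dataclass
class AnimalModelResults:
    """REML estimates, BLUP solutions and diagnostics for an AnimalModel."""

    model: AnimalModel
    vc: VarianceComponents
    b: np.ndarray
    u: np.ndarray

    @property
    def sigma_u2(self):
        return self.vc.sigma_u2

    @property
    def sigma_e2(self):
        return self.vc.sigma_e2

    @property
    def h2(self):
        return self.vc.h2

    @property
    def loglik(self):
        return self.vc.loglik

    def summary(self) -> str:
        vc = self.vc
        lines = [
            "Animal model REML results",
            "=" * 46,
            f"records:            {self.model.y.size}",
            f"animals in kinship: {self.model.kinship.shape[0]}",
            f"fixed effects:      {self.model.X.shape[1]}",
            f"iterations:         {vc.n_iter}   (converged)",
            f"log-likelihood:     {vc.loglik:.4f}",
            "-" * 46,
            f"sigma_u^2 (additive): {vc.sigma_u2:10.4f}  SE {vc.se_sigma_u2:.4f}",
            f"sigma_e^2 (residual): {vc.sigma_e2:10.4f}  SE {vc.se_sigma_e2:.4f}",
            f"h^2:                  {vc.h2:10.4f}  SE {vc.se_h2:.4f}",
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
# bivariate REML
# ----------------------------------------------------------------------

@dataclass
class BivariateComponents:
    """Two-trait (co)variance estimates with correlations and SEs."""

    G0: np.ndarray
    R0: np.ndarray
    genetic_correlation: float
    residual_correlation: float
    se_genetic_correlation: float
    se_residual_correlation: float
    h2: tuple[float, float]
    loglik: float
    converged: bool
    n_iter: int


def _chol_from_params(phi):
    l11, l21, l22 = np.exp(phi[0]), phi[1], np.exp(phi[2])
    return np.array([[l11, 0.0], [l21, l22]])


def _biv_negloglik(phi, lam, Yt, Xt):
    if np.any(np.abs(phi) > 40):  # guard against runaway steps
        return 1e10
    Lg = _chol_from_params(phi[:3])
    Lr = _chol_from_params(phi[3:])
    G0 = Lg @ Lg.T
    R0 = Lr @ Lr.T
    n, p = Xt.shape
    s11 = G0[0, 0] * lam + R0[0, 0]
    s12 = G0[0, 1] * lam + R0[0, 1]
    s22 = G0[1, 1] * lam + R0[1, 1]
    det = s11 * s22 - s12**2
    if (det <= 0).any() or (s11 <= 0).any():
        return 1e10
    w11, w12, w22 = s22 / det, -s12 / det, s11 / det
    y1, y2 = Yt[:, 0], Yt[:, 1]
    B11 = Xt.T @ (Xt * w11[:, None])
    B12 = Xt.T @ (Xt * w12[:, None])
    B22 = Xt.T @ (Xt * w22[:, None])
    B = np.block([[B11, B12], [B12.T, B22]])
    c = np.concatenate([Xt.T @ (w11 * y1 + w12 * y2), Xt.T @ (w12 * y1 + w22 * y2)])
    sign, logdet_b = np.linalg.slogdet(B)
    if sign <= 0:
        return 1e10
    try:
        b = np.linalg.solve(B, c)
    except np.linalg.LinAlgError:
        return 1e10
    yvy = float(w11 @ y1**2 + 2.0 * (w12 @ (y1 * y2)) + w22 @ y2**2)
    quad = yvy - float(c @ b)
    return 0.5 * (float(np.sum(np.log(det))) + logdet_b + quad)


def reml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    X: np.ndarray,
    M: np.ndarray,
    maxiter: int = 500,
) -> BivariateComponents:
    """Two-trait REML with G0, R0 parameterised by Cholesky factors.

    Both traits must be recorded on the same animals with the same fixed
    design (complete cases).  The eigenrotation of M decouples records; the
    6 Cholesky parameters are maximised with L-BFGS-B, SEs come from the
    numerical observed information and the delta method.  Correlations at
    the rg -> 1 boundary are handled by bounding the Cholesky diagonals
    away from zero.
    """
    Y = np.column_stack([np.asarray(y1, float), np.asarray(y2, float)])
    # fit on standardized traits (scale-free parameters); scale back after
    sdev = Y.std(axis=0, ddof=1)
    Y = Y / sdev
    rot = _Rotation(np.asarray(M, float), np.asarray(X, float), Y)
    lam, Yt, Xt = rot.lam, rot.Yt, rot.Xt

    # start values: single-trait REML per trait, covariances from the
    # phenotypic correlation of OLS residuals
    vc1 = reml_single(Y[:, 0], X, M)
    vc2 = reml_single(Y[:, 1], X, M)
    Q, _ = np.linalg.qr(X)
    R1 = Y[:, 0] - Q @ (Q.T @ Y[:, 0])
    R2 = Y[:, 1] - Q @ (Q.T @ Y[:, 1])
    rp = float(np.corrcoef(R1, R2)[0, 1]) * 0.9
    G0 = np.array(
        [
            [vc1.sigma_u2, rp * np.sqrt(vc1.sigma_u2 * vc2.sigma_u2)],
            [rp * np.sqrt(vc1.sigma_u2 * vc2.sigma_u2), vc2.sigma_u2],
        ]
    )
    R0 = np.array(
        [
            [vc1.sigma_e2, rp * np.sqrt(vc1.sigma_e2 * vc2.sigma_e2)],
            [rp * np.sqrt(vc1.sigma_e2 * vc2.sigma_e2), vc2.sigma_e2],
        ]
    )

    def params_from(Mx):
        L = np.linalg.cholesky(Mx)
        return [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])]

    phi0 = np.array(params_from(G0) + params_from(R0))
    scale = np.sqrt(np.var(Y, axis=0, ddof=1))
    lb = np.log(1e-5 * min(scale))
    bounds = [(lb, None), (None, None), (lb, None)] * 2

    res = optimize.minimize(
        _biv_negloglik,
        phi0,
        args=(lam, Yt, Xt),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    phi = res.x
    Lg, Lr = _chol_from_params(phi[:3]), _chol_from_params(phi[3:])
    S = np.diag(sdev)
    G0, R0 = S @ (Lg @ Lg.T) @ S, S @ (Lr @ Lr.T) @ S

    def corr(Mx):
        return float(Mx[0, 1] / np.sqrt(Mx[0, 0] * Mx[1, 1]))

    # delta-method SEs from the numerical observed information
    def corr_of_phi(ph, block):
        L = _chol_from_params(ph[block : block + 3])
        C = L @ L.T
        return corr(C)

    h = 1e-4 * np.maximum(np.abs(phi), 1.0)
    k = len(phi)
    H = np.zeros((k, k))
    f0 = _biv_negloglik(phi, lam, Yt, Xt)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = _biv_negloglik(phi + ei + ej, lam, Yt, Xt)
            fpm = _biv_negloglik(phi + ei - ej, lam, Yt, Xt)
            fmp = _biv_negloglik(phi - ei + ej, lam, Yt, Xt)
            fmm = _biv_negloglik(phi - ei - ej, lam, Yt, Xt)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)

    def corr_se(block):
        g = np.zeros(k)
        for i in range(block, block + 3):
            ei = np.zeros(k); ei[i] = h[i]
            g[i] = (corr_of_phi(phi + ei, block) - corr_of_phi(phi - ei, block)) / (2 * h[i])
        v = float(g @ cov @ g)
        return float(np.sqrt(v)) if np.isfinite(v) and v > 0 else float("nan")

    h2 = (
        float(G0[0, 0] / (G0[0, 0] + R0[0, 0])),
        float(G0[1, 1] / (G0[1, 1] + R0[1, 1])),
    )
    return BivariateComponents(
        G0=G0,
        R0=R0,
        genetic_correlation=corr(G0),
        residual_correlation=corr(R0),
        se_genetic_correlation=corr_se(0),
        se_residual_correlation=corr_se(3),
        h2=h2,
        loglik=float(-f0),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )


class BivariateAnimalModel:
    """Two-trait animal model (pedigree kinship) fitted by REML."""

    def __init__(self, y1, y2, X, kinship, rec_idx):
        self.y1 = np.asarray(y1, float)
        self.y2 = np.asarray(y2, float)
        self.X = np.asarray(X, float)
        self.kinship = np.asarray(kinship, float)
        self.rec_idx = np.asarray(rec_idx, np.int64)

    @classmethod
    def from_dataframe(
        cls,
        phenotypes: pd.DataFrame,
        traits: tuple[str, str],
        pedigree: Pedigree,
        kinship: np.ndarray | None = None,
        cg_col: str = "cg",
        age_col: str = "age",
        animal_col: str = "animal_id",
    ) -> "BivariateAnimalModel":
        t1, t2 = traits
        ok = np.isfinite(phenotypes[t1].to_numpy(float)) & np.isfinite(
            phenotypes[t2].to_numpy(float)
        )
        data = phenotypes[ok]
        X, names, rec_idx = build_design(data, cg_col, age_col, animal_col, pedigree)
        K = kinship if kinship is not None else nrm(pedigree).matrix
        return cls(data[t1].to_numpy(float), data[t2].to_numpy(float), X, K, rec_idx)

    def fit(self, maxiter: int = 500) -> BivariateComponents:
        M = self.kinship[np.ix_(self.rec_idx, self.rec_idx)]
        return reml_bivariate(self.y1, self.y2, self.X, M, maxiter=maxiter)
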