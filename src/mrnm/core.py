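"""The bivariate reaction norm mixed model and its REML machinery.

Model.  For standardized residual traits Y (outcome) and C (covariate) on n
individuals with genomic relationship matrix K and covariate gradient
c = C, the stacked vector (Y, C) is multivariate normal with mean X b and
covariance built from six random effects: polygenic intercepts alpha0
(for Y) and beta0 (for C), a polygenic slope alpha1 on c (the G-C
interaction), residual intercepts tau0 / eps0, and a residual slope tau1 on
c (the R-C interaction).  With D = diag(c):

    V_YY = s2_a0*K + s_a0a1*(KD + DK) + s2_a1*D K D
         + s2_t0*I + 2*s_t0t1*D + s2_t1*D^2
    V_YC = s_a0b0*K + s_a1b0*D K + s_t0e0*I + s_t1e0*D
    V_CC = s2_b0*K + s2_e0*I

The null model (bivariate GREML) drops every term containing alpha1 or
tau1.  All components are estimated unconstrained in sign.

Fitting is average-information REML: after a few damped stabilising
updates, full AI steps with step-halving whenever a proposed step leaves
the positive-definite cone or decreases the restricted likelihood.
Standard errors come from the inverse of the average-information matrix at
convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri

from mrnm.errors import (
    AlignmentError,
    InitializationError,
    NotPositiveDefiniteError,
    ParameterError,
)

FULL_PARAMS: tuple[str, ...] = (
    "var_a0", "cov_a0a1", "var_a1", "cov_a0b0", "cov_a1b0", "var_b0",
    "var_t0", "cov_t0t1", "var_t1", "cov_t0e0", "cov_t1e0", "var_e0",
)
NULL_PARAMS: tuple[str, ...] = (
    "var_a0", "cov_a0b0", "var_b0", "var_t0", "cov_t0e0", "var_e0",
)

# each parameter multiplies one structured matrix: (block, kind)
_FULL_STRUCTURE = (
    ("YY", "K"), ("YY", "KD+DK"), ("YY", "DKD"),
    ("YC", "K"), ("YC", "DK"), ("CC", "K"),
    ("YY", "I"), ("YY", "2D"), ("YY", "D2"),
    ("YC", "I"), ("YC", "D"), ("CC", "I"),
)
_NULL_STRUCTURE = (
    ("YY", "K"), ("YC", "K"), ("CC", "K"),
    ("YY", "I"), ("YC", "I"), ("CC", "I"),
)


@dataclass
class MRNMParams:
    """Random-effect (co)variance parameters of a null or full MRNM.

    ``values`` is ordered as ``param_names``; entries are unconstrained in
    sign.  The genetic block covers (alpha0, alpha1, beta0) and the
    residual block (tau0, tau1, eps0); in the null model the slope rows are
    structurally absent (6 parameters instead of 12).
    """

    model: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.model not in ("null", "full"):
            raise ParameterError(f"unknown model tag {self.model!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.param_names):
            raise ParameterError(
                f"{self.model} model has {len(self.param_names)} parameters, "
                f"got {self.values.size}"
            )

    @property
    def param_names(self) -> tuple[str, ...]:
        return FULL_PARAMS if self.model == "full" else NULL_PARAMS

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.param_names.index(name)])

    @classmethod
    def from_matrices(cls, sigma_g: np.ndarray, sigma_e: np.ndarray) -> "MRNMParams":
        """Full-model parameters from 3x3 genetic / residual covariance
        matrices over (alpha0, alpha1, beta0) and (tau0, tau1, eps0)."""
        sigma_g = np.asarray(sigma_g, dtype=float)
        sigma_e = np.asarray(sigma_e, dtype=float)
        for mat, tag in ((sigma_g, "genetic"), (sigma_e, "residual")):
            if mat.shape != (3, 3) or not np.allclose(mat, mat.T):
                raise ParameterError(f"{tag} covariance must be symmetric 3x3")
        vals = [
            sigma_g[0, 0], sigma_g[0, 1], sigma_g[1, 1],
            sigma_g[0, 2], sigma_g[1, 2], sigma_g[2, 2],
            sigma_e[0, 0], sigma_e[0, 1], sigma_e[1, 1],
            sigma_e[0, 2], sigma_e[1, 2], sigma_e[2, 2],
        ]
        return cls(model="full", values=np.array(vals))

    def to_full_vector(self) -> np.ndarray:
        """Embed into the 12-entry full-model order (slope entries zero)."""
        if self.model == "full":
            return self.values.copy()
        out = np.zeros(12)
        for name, v in zip(NULL_PARAMS, self.values):
            out[FULL_PARAMS.index(name)] = v
        return out


@dataclass
class MRNMFit:
    """Result of an AI-REML fit: estimates, SEs, likelihood, diagnostics."""

    params: MRNMParams
    se: np.ndarray
    loglik: float
    ai_matrix: np.ndarray | None
    ai_inverse: np.ndarray | None
    converged: bool
    n_iter: int
    n: int
    history: list = field(default_factory=list)
    subgroup: str = ""
    notes: str = ""
    min_pivot_sq: float = float("nan")  # smallest squared Cholesky pivot of V-hat

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.params.param_names

    def estimate(self, name: str) -> float:
        return self.params[name]

    def se_of(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])

    def to_dict(self) -> dict:
        return {
            "model": self.params.model,
            "params": dict(zip(self.param_names, self.params.values.tolist())),
            "se": dict(zip(self.param_names, np.asarray(self.se).tolist())),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n": self.n,
            "subgroup": self.subgroup,
        }


class _Structure:
    """Structured derivative matrices dV/dtheta for one model on one dataset.

    V is linear in the parameters, so each derivative is a fixed matrix
    determined by K and c; blocks are kept in factored (dense or diagonal)
    form to keep traces and matrix-vector products at O(n^2).
    """

    def __init__(self, K: np.ndarray, c: np.ndarray, model: str) -> None:
        self.n = K.shape[0]
        self.model = model
        self.spec = _FULL_STRUCTURE if model == "full" else _NULL_STRUCTURE
        self.K = K
        self.c = c
        cK = c[:, None] * K
        Kc = K * c[None, :]
        self._dense = {
            ("YY", "K"): K,
            ("YY", "KD+DK"): Kc + cK,
            ("YY", "DKD"): c[:, None] * Kc,
            ("YC", "K"): K,
            ("YC", "DK"): cK,
            ("CC", "K"): K,
        }
        ones = np.ones(self.n)
        self._diag = {
            ("YY", "I"): ones,
            ("YY", "2D"): 2.0 * c,
            ("YY", "D2"): c ** 2,
            ("YC", "I"): ones,
            ("YC", "D"): c,
            ("CC", "I"): ones,
        }

    @property
    def n_params(self) -> int:
        return len(self.spec)

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        n = self.n
        V = np.zeros((2 * n, 2 * n))
        for t, key in zip(theta, self.spec):
            block, kind = key
            if key in self._dense:
                M = t * self._dense[key]
                if block == "YY":
                    V[:n, :n] += M
                elif block == "CC":
                    V[n:, n:] += M
                else:
                    V[:n, n:] += M
                    V[n:, :n] += M.T
            else:
                d = t * self._diag[key]
                if block == "YY":
                    V[:n, :n][np.diag_indices(n)] += d
                elif block == "CC":
                    V[n:, n:][np.diag_indices(n)] += d
                else:
                    V[:n, n:][np.diag_indices(n)] += d
                    V[n:, :n][np.diag_indices(n)] += d
        return V

    def trace_with(self, P: np.ndarray, j: int) -> float:
        """tr(P dV/dtheta_j) using the block structure of the derivative."""
        n = self.n
        key = self.spec[j]
        block, _ = key
        if block == "YY":
            Pb = P[:n, :n]
            factor = 1.0
        elif block == "CC":
            Pb = P[n:, n:]
            factor = 1.0
        else:
            Pb = P[:n, n:]
            factor = 2.0
        if key in self._dense:
            return factor * float(np.sum(Pb * self._dense[key]))
        return factor * float(np.dot(np.diagonal(Pb), self._diag[key]))

    def matvec(self, j: int, w: np.ndarray) -> np.ndarray:
        """(dV/dtheta_j) @ w for a stacked 2n-vector w."""
        n = self.n
        key = self.spec[j]
        block, _ = key
        out = np.zeros_like(w)
        if key in self._dense:
            M = self._dense[key]
            if block == "YY":
                out[:n] = M @ w[:n]
            elif block == "CC":
                out[n:] = M @ w[n:]
            else:
                out[:n] = M @ w[n:]
                out[n:] = M.T @ w[:n]
        else:
            d = self._diag[key]
            if block == "YY":
                out[:n] = d * w[:n]
            elif block == "CC":
                out[n:] = d * w[n:]
            else:
                out[:n] = d * w[n:]
                out[n:] = d * w[:n]
        return out


def _align(K, c, *vectors):
    from mrnm.grm import GRM
    from mrnm.covariate_prep import AdjustedTrait

    if isinstance(K, GRM):
        ids = K.sample_ids
        Km = K.matrix
    else:
        ids = None
        Km = np.asarray(K, dtype=float)
    if isinstance(c, AdjustedTrait):
        if ids is not None and c.sample_ids != ids:
            if set(c.sample_ids) != set(ids):
                raise AlignmentError("GRM and covariate ids do not match")
            c = c.subset(ids)
        cv = c.values
    else:
        cv = np.asarray(c, dtype=float)
    outs = []
    for v in vectors:
        if isinstance(v, AdjustedTrait):
            if ids is not None and v.sample_ids != ids:
                if set(v.sample_ids) != set(ids):
                    raise AlignmentError("GRM and trait ids do not match")
                v = v.subset(ids)
            outs.append(v.values)
        else:
            outs.append(np.asarray(v, dtype=float))
    if Km.shape[0] != cv.size:
        raise AlignmentError(
            f"GRM of size {Km.shape[0]} vs covariate of length {cv.size}"
        )
    return (Km, cv, *outs)


def build_covariance(params: MRNMParams, K, c) -> np.ndarray:
    """Dense 2n x 2n covariance of the stacked (Y, C) vector."""
    Km, cv = _align(K, c)
    structure = _Structure(Km, cv, params.model)
    return structure.build_V(params.values)


def default_design(n: int) -> np.ndarray:
    """Per-trait intercepts for the stacked (Y, C) vector."""
    X = np.zeros((2 * n, 2))
    X[:n, 0] = 1.0
    X[n:, 1] = 1.0
    return X


def _reml_pieces(V: np.ndarray, X: np.ndarray, y: np.ndarray,
                 min_pivot: float = 0.0):
    try:
        cf = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(str(exc)) from exc
    if min_pivot > 0.0 and float(np.min(np.diag(cf[0]))) < min_pivot:
        raise NotPositiveDefiniteError("Cholesky pivot below PD margin")
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ViX = cho_solve(cf, X, check_finite=False)
    Viy = cho_solve(cf, y, check_finite=False)
    XtViX = X.T @ ViX
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise NotPositiveDefiniteError("X'V^-1X not positive definite")
    Py = Viy - ViX @ np.linalg.solve(XtViX, X.T @ Viy)
    ll = -0.5 * (logdet_V + logdet_XtViX + float(y @ Py))
    return cf, ViX, XtViX, Py, ll


def reml_loglik(params: MRNMParams, K, c, y_stacked: np.ndarray,
                X: np.ndarray | None = None) -> float:
    """Restricted log-likelihood of the stacked data under ``params``.

    Convention: ``-1/2 [log|V| + log|X'V^-1 X| + y'Py]`` with the additive
    constant ``-(2n - p)/2 log(2 pi)`` dropped; differences of values share
    the same constant for fixed n and X.  Raises
    ``NotPositiveDefiniteError`` when V is not PD (never regularized
    silently).
    """
    Km, cv, y = _align(K, c, y_stacked)
    if X is None:
        X = default_design(Km.shape[0])
    V = _Structure(Km, cv, params.model).build_V(params.values)
    *_, ll = _reml_pieces(V, X, np.asarray(y, dtype=float))
    return ll


def _default_init(model: str) -> np.ndarray:
    """Near-diagonal start on the standardized scale (config-exposed)."""
    if model == "full":
        p = np.zeros(12)
        p[[0, 5]] = 0.3   # polygenic intercept variances
        p[2] = 0.05       # polygenic slope variance
        p[[6, 11]] = 0.7  # residual intercept variances
        p[8] = 0.05       # residual slope variance
        return p
    p = np.zeros(6)
    p[[0, 2]] = 0.3
    p[[3, 5]] = 0.7
    return p


def warm_start_from_null(null_fit: "MRNMFit", slope_var: float = 0.01
                         ) -> np.ndarray:
    """Full-model initialization embedding a fitted null model.

    Slope variances start at a small positive value so their AI rows are
    informative from the first iteration.
    """
    vec = null_fit.params.to_full_vector()
    vec[FULL_PARAMS.index("var_a1")] = slope_var
    vec[FULL_PARAMS.index("var_t1")] = slope_var
    return vec


def fit_mrnm(
    K,
    Y,
    C,
    model: str = "full",
    init: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    n_warmup: int = 3,
    max_halvings: int = 10,
    min_n: int = 100,
    pd_margin: float = 1e-2,
    subgroup: str = "",
) -> MRNMFit:
    """Fit a null or full MRNM by average-information REML.

    ``Y`` and ``C`` are standardized adjusted traits (or plain vectors)
    aligned with the GRM; the covariate gradient is C itself.  The first
    ``n_warmup`` iterations use a damped information matrix for stability;
    afterwards full AI steps are taken with step-halving (up to
    ``max_halvings``) whenever a step leaves the PD cone or lowers the
    restricted likelihood.  Components are unconstrained in sign, but the
    implied covariance is kept inside the positive-definite cone with a
    small margin (``pd_margin`` on the squared-Cholesky-pivot scale, i.e.
    roughly on the eigenvalue scale of the standardized-trait V): without
    it the restricted likelihood can harvest spurious gains by crawling
    along the singular-V ridge in small samples, inflating the full-vs-null
    likelihood ratio statistic under the null.
    """
    Km, cv, yv, Cv = _align(K, C, Y, C)
    n = Km.shape[0]
    if n < min_n:
        raise ParameterError(f"n = {n} below the configured minimum {min_n}")
    y = np.concatenate([yv, Cv])
    X = default_design(n)
    structure = _Structure(Km, cv, model)
    q = structure.n_params
    theta = np.asarray(init, dtype=float).copy() if init is not None \
        else _default_init(model)
    if theta.size != q:
        raise ParameterError(f"init has {theta.size} entries, model needs {q}")

    min_pivot = float(np.sqrt(pd_margin)) if pd_margin > 0 else 0.0

    try:
        V = structure.build_V(theta)
        cf, ViX, XtViX, Py, ll = _reml_pieces(V, X, y, min_pivot)
    except NotPositiveDefiniteError as exc:
        raise InitializationError(
            f"covariance not PD at initialization: {exc}"
        ) from exc

    def inverse_from_factor(factor):
        # dpotri computes the inverse from the Cholesky factor in half the
        # flops of a full solve against the identity
        # dpotri writes only the requested triangle; the other half still
        # holds factorization workspace and must be discarded
        inv, info = dpotri(factor[0], lower=True)
        if info != 0:
            raise NotPositiveDefiniteError("dpotri failed")
        low = np.tril(inv)
        return low + np.tril(inv, -1).T

    history = [ll]
    converged = False
    notes = []
    it = 0
    for it in range(1, max_iter + 1):
        # P explicit: Vinv - ViX (X'ViX)^-1 ViX'
        Vinv = inverse_from_factor(cf)
        P = Vinv - ViX @ np.linalg.solve(XtViX, ViX.T)

        grad = np.empty(q)
        U = np.empty((2 * n, q))
        for j in range(q):
            U[:, j] = structure.matvec(j, Py)
            grad[j] = -0.5 * (structure.trace_with(P, j) - float(Py @ U[:, j]))
        AI = 0.5 * (U.T @ (P @ U))
        AI = 0.5 * (AI + AI.T)

        # propose one step per Levenberg-style damping level (0 is the
        # plain AI step; high damping approaches a scaled gradient step),
        # halve each until it enters the PD cone and improves, then take
        # the best proposal.  Convergence is declared only when the best
        # achievable improvement falls below tol.
        dampings = [0.0, 0.1, 1.0, 10.0, 100.0]
        if it <= n_warmup:
            dampings = dampings[1:]
        best = None
        for damping in dampings:
            AI_step = AI.copy()
            AI_step[np.diag_indices(q)] += damping * (np.abs(np.diag(AI)) + 1e-3)
            try:
                delta = np.linalg.solve(AI_step, grad)
            except np.linalg.LinAlgError:
                delta = np.linalg.pinv(AI_step) @ grad
            step = 1.0
            # a correct score guarantees ascent for small enough steps
            n_halve = max(max_halvings + 1, 40)
            for _ in range(n_halve):
                cand = theta + step * delta
                try:
                    V_new = structure.build_V(cand)
                    pieces = _reml_pieces(V_new, X, y, min_pivot)
                except NotPositiveDefiniteError:
                    step *= 0.5
                    continue
                if pieces[-1] >= ll - 1e-10:
                    if best is None or pieces[-1] > best[1][-1]:
                        best = (cand, pieces)
                    break
                step *= 0.5
            # solidly improving proposal found: skip higher dampings
            if best is not None and best[1][-1] - ll >= 10.0 * tol:
                break
        if best is None:
            notes.append(f"iter {it}: no improving step found")
            converged = np.linalg.norm(grad) < 1e-3 * (1 + abs(ll))
            break
        cand, (cf_new, ViX_new, XtViX_new, Py_new, ll_new) = best
        d_ll = ll_new - ll
        theta, cf, ViX, XtViX, Py, ll = cand, cf_new, ViX_new, XtViX_new, Py_new, ll_new
        history.append(ll)
        if it > n_warmup and abs(d_ll) < tol:
            converged = True
            break

    # SEs from the AI matrix at the final parameters
    Vinv = inverse_from_factor(cf)
    P = Vinv - ViX @ np.linalg.solve(XtViX, ViX.T)
    U = np.empty((2 * n, q))
    for j in range(q):
        U[:, j] = structure.matvec(j, Py)
    AI = 0.5 * (U.T @ (P @ U))
    AI = 0.5 * (AI + AI.T)
    cond = np.linalg.cond(AI)
    if cond > 1e10:
        notes.append(f"AI matrix ill-conditioned (cond {cond:.2e}); pseudo-inverse SEs")
        ai_inv = np.linalg.pinv(AI)
    else:
        ai_inv = np.linalg.inv(AI)
    diag = np.diag(ai_inv).copy()
    bad = diag < 0
    if bad.any():
        notes.append("negative AI-inverse diagonal entries; SEs set to NaN there")
        diag[bad] = np.nan
    se = np.sqrt(diag)

    return MRNMFit(
        params=MRNMParams(model=model, values=theta),
        se=se,
        loglik=ll,
        ai_matrix=AI,
        ai_inverse=ai_inv,
        converged=converged,
        n_iter=it,
        n=n,
        history=history,
        subgroup=subgroup,
        notes="; ".join(notes),
        min_pivot_sq=float(np.min(np.diag(cf[0])) ** 2),
    )


# ---------------------------------------------------------------------------
# Reporting on the fitted components


_COMPONENTS = ("var_a0", "var_a1", "var_t0", "var_t1")


def variance_proportions(fit: MRNMFit, z: float = 1.959963984540054) -> dict:
    """The four variance components as percentages of Var[Y].

    On the standardized scale the marginal outcome variance is 1 for a
    standardized covariate gradient, so each component maps directly to a
    percentage.  SEs are delta-method (identity map) from the AI-inverse;
    negative point estimates are reported as-is, with a flag marking CIs
    that straddle zero.
    """
    out = {}
    have_se = fit.ai_inverse is not None
    for name in _COMPONENTS:
        if fit.params.model == "null" and name not in fit.param_names:
            continue
        est = 100.0 * fit.estimate(name)
        if have_se:
            se = 100.0 * fit.se_of(name)
            ci = (est - z * se, est + z * se)
            out[name] = {
                "pct": est,
                "se": se,
                "ci": ci,
                "excludes_zero": not (ci[0] <= 0.0 <= ci[1]),
            }
        else:
            out[name] = {"pct": est, "se": None, "ci": None, "excludes_zero": None}
    return out


@dataclass
class VarianceCurve:
    """Variance components of the outcome as functions of the covariate."""

    c_grid: np.ndarray
    var_genetic: np.ndarray
    se_genetic: np.ndarray
    var_residual: np.ndarray
    se_residual: np.ndarray
    var_total: np.ndarray
    se_total: np.ndarray
    extrapolated: np.ndarray

    def band(self, which: str = "genetic", z: float = 1.959963984540054):
        v = getattr(self, f"var_{which}")
        s = getattr(self, f"se_{which}")
        return v - z * s, v + z * s


def variance_function(
    fit: MRNMFit,
    c_grid: np.ndarray,
    c_observed: np.ndarray | None = None,
) -> VarianceCurve:
    """Evaluate Var_g(c) = s2_a0 + 2c s_a0a1 + c^2 s2_a1 and the residual
    analogue on a grid, with pointwise delta-method standard errors.

    The gradient of each curve w.r.t. its three parameters is (1, 2c, c^2);
    pointwise variance is g' Cov g with Cov taken from the AI-inverse.
    Grid points outside the observed covariate range are flagged.
    """
    if fit.params.model != "full":
        raise ParameterError("variance curves require a full-model fit")
    grid = np.asarray(c_grid, dtype=float)
    names = fit.param_names
    gi = [names.index(k) for k in ("var_a0", "cov_a0a1", "var_a1")]
    ri = [names.index(k) for k in ("var_t0", "cov_t0t1", "var_t1")]
    th = fit.params.values
    G = np.column_stack([np.ones_like(grid), 2.0 * grid, grid ** 2])
    var_g = G @ th[gi]
    var_r = G @ th[ri]
    if fit.ai_inverse is not None:
        cov_g = fit.ai_inverse[np.ix_(gi, gi)]
        cov_r = fit.ai_inverse[np.ix_(ri, ri)]
        cov_gr = fit.ai_inverse[np.ix_(gi, ri)]
        se_g = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, cov_g, G), 0.0))
        se_r = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, cov_r, G), 0.0))
        tot = (
            np.einsum("ij,jk,ik->i", G, cov_g, G)
            + np.einsum("ij,jk,ik->i", G, cov_r, G)
            + 2.0 * np.einsum("ij,jk,ik->i", G, cov_gr, G)
        )
        se_t = np.sqrt(np.maximum(tot, 0.0))
    else:
        se_g = se_r = se_t = np.full_like(grid, np.nan)
    if c_observed is not None:
        lo, hi = float(np.min(c_observed)), float(np.max(c_observed))
        extrapolated = (grid < lo) | (grid > hi)
    else:
        extrapolated = np.zeros_like(grid, dtype=bool)
    return VarianceCurve(
        c_grid=grid,
        var_genetic=var_g,
        se_genetic=se_g,
        var_residual=var_r,
        se_residual=se_r,
        var_total=var_g + var_r,
        se_total=se_t,
        extrapolated=extrapolated,
    )
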