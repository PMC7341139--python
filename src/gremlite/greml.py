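"""GREML variance-component estimation by average-information REML.

Univariate model:  y = X b + u + e,  Var(u) = G su2,  Var(e) = I se2,
with y the sex- and age-adjusted z-scores, X the fixed-effect design
(intercept, batch dummies, principal components) and G the genomic
relationship matrix.  SNP heritability is h2 = su2 / (su2 + se2).

Bivariate model: the two trait vectors are stacked, Var(u) has blocks
g_ij * G and Var(e) blocks r_ij (r12 only for individuals with both
traits); the genetic correlation is rg = g12 / sqrt(g11 g22).

Restricted log-likelihood (constants dropped):

    lR = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P  = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

AI-REML iterates theta <- theta + AI^-1 s with score
s_i = -1/2 [tr(P A_i) - y' P A_i P y] and average information
AI_ij = 1/2 y' P A_i P A_j P y, where A_i = dV/dtheta_i.  The first
univariate step is EM-REML; AI steps are halved whenever the restricted
likelihood would decrease, so accepted iterations never reduce it.
Variance components are clamped at 1e-6 times the phenotypic variance.

When both traits share one individual set, a one-time eigendecomposition
of G reduces every iteration to O(n p^2): in the rotated basis V is
diagonal (univariate) or 2x2-block-diagonal (bivariate).  A direct dense
evaluation of the same quantities is kept as an independent path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.stats import chi2

from .grm_pca import GRM

_VAR_FLOOR_FRAC = 1e-6  # boundary clamp as a fraction of phenotypic variance
PARAM_NAMES_BIVAR = ("g11", "g12", "g22", "r11", "r12", "r22")


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

def _check_full_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design matrix is rank-deficient")


@dataclass
class MixedModelData:
    """Aligned response, fixed-effects design and GRM for one trait."""

    y: np.ndarray
    X: np.ndarray
    G: np.ndarray
    ids: np.ndarray | None = None
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        n = self.y.size
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise ValueError("X must be n x p")
        if self.G.shape != (n, n):
            raise ValueError("G must be n x n")
        if self.ids is None:
            self.ids = np.arange(n)
        _check_full_rank(self.X)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def eig(self):
        """Cached eigendecomposition of G with rotated y and X."""
        if self._eig is None:
            w, U = scipy.linalg.eigh(self.G)
            w = np.maximum(w, 0.0)  # G is PSD up to round-off
            self._eig = (w, U, U.T @ self.y, U.T @ self.X)
        return self._eig


def make_design(covars: pd.DataFrame | None = None,
                pcs: np.ndarray | None = None,
                n: int | None = None) -> np.ndarray:
    """Intercept + dummy-coded categorical covariates + PC columns.

    Categorical columns are dummy-coded dropping the first level; constant
    columns are dropped (a single batch level carries no information).
    """
    blocks = []
    if covars is not None:
        n = len(covars)
        for col in covars.columns:
            d = pd.get_dummies(covars[col].astype("category"), drop_first=True)
            if d.shape[1]:
                blocks.append(d.to_numpy(dtype=float))
    if n is None and pcs is not None:
        n = len(pcs)
    if n is None:
        raise ValueError("cannot infer sample size for the design matrix")
    if pcs is not None:
        blocks.append(np.asarray(pcs, dtype=float))
    X = np.column_stack([np.ones(n)] + blocks) if blocks else np.ones((n, 1))
    _check_full_rank(X)
    return X


# ---------------------------------------------------------------------------
# univariate restricted likelihood
# ---------------------------------------------------------------------------

def _uni_eval(theta, data: MixedModelData):
    """All per-iteration quantities at theta = (su2, se2), eigen basis."""
    su2, se2 = theta
    w, _, yt, Xt = data.eig()
    d = su2 * w + se2
    if (d <= 0).any():
        raise ValueError("singular covariance matrix V")
    Wd = Xt / d[:, None]
    XtVX = Xt.T @ Wd
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise ValueError("X' V^-1 X not positive definite")
    cf = scipy.linalg.cho_factor(XtVX)

    def apply_P(v):
        return v / d - Wd @ scipy.linalg.cho_solve(cf, Wd.T @ v)

    q = apply_P(yt)
    ypy = float(yt @ q)
    ll = -0.5 * (np.log(d).sum() + logdet_xvx + ypy)

    def tr_P_times(a):  # a: diagonal of A in the eigen basis
        t1 = (a / d).sum()
        m = Wd.T @ (a[:, None] * Wd)
        return t1 - np.trace(scipy.linalg.cho_solve(cf, m))

    tu = w * q
    te = q
    Ptu, Pte = apply_P(tu), apply_P(te)
    ai = 0.5 * np.array([[tu @ Ptu, tu @ Pte], [te @ Ptu, te @ Pte]])
    tr_pg = tr_P_times(w)
    tr_pi = tr_P_times(np.ones_like(w))
    score = np.array([
        -0.5 * (tr_pg - q @ tu),
        -0.5 * (tr_pi - q @ te),
    ])
    return {"ll": ll, "q": q, "score": score, "ai": ai,
            "tr_PG": tr_pg, "tr_PI": tr_pi, "w": w}


def reml_loglik(theta, data: MixedModelData, method: str = "eig") -> float:
    """Restricted log-likelihood at theta = (su2, se2) (constants dropped)."""
    su2, se2 = theta
    if su2 < 0 or se2 <= 0:
        raise ValueError("require su2 >= 0 and se2 > 0")
    if method == "eig":
        return _uni_eval(theta, data)["ll"]
    if method != "direct":
        raise ValueError("method must be 'eig' or 'direct'")
    V = su2 * data.G + se2 * np.eye(data.n)
    try:
        cf = scipy.linalg.cho_factor(V)
    except scipy.linalg.LinAlgError as err:
        raise ValueError("singular covariance matrix V") from err
    logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
    ViX = scipy.linalg.cho_solve(cf, data.X)
    XtVX = data.X.T @ ViX
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise ValueError("X' V^-1 X not positive definite")
    Viy = scipy.linalg.cho_solve(cf, data.y)
    beta = np.linalg.solve(XtVX, data.X.T @ Viy)
    ypy = float(data.y @ (Viy - ViX @ beta))
    return -0.5 * (logdet_v + logdet_xvx + ypy)


def null_reml_loglik(data: MixedModelData) -> float:
    """Restricted log-likelihood of the su2 = 0 model, maximized over se2."""
    n, p = data.n, data.p
    beta, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    rss = float(np.sum((data.y - data.X @ beta) ** 2))
    se2 = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(data.X.T @ data.X)
    return -0.5 * ((n - p) * np.log(se2) + logdet_xtx + (n - p))


# ---------------------------------------------------------------------------
# univariate AI-REML
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    cov: np.ndarray
    loglik_reml: float
    n_iter: int
    converged: bool
    loglik_trace: list = field(default_factory=list)


def ai_reml_fit(data: MixedModelData, init=None, tol: float = 1e-4,
                max_iter: int = 100) -> VarianceComponents:
    """Univariate AI-REML fit of (su2, se2).

    First step is EM-REML; subsequent AI steps are halved if the restricted
    likelihood would decrease.  Components are clamped at 1e-6 * Var(y).
    """
    n, p = data.n, data.p
    if n <= p + 2:
        raise ValueError("too few observations for the fixed-effect design")
    vp = float(np.var(data.y, ddof=1))
    floor = _VAR_FLOOR_FRAC * vp
    theta = np.array(init, dtype=float) if init is not None \
        else np.array([0.5 * vp, 0.5 * vp])
    theta = np.maximum(theta, floor)

    state = _uni_eval(theta, data)
    trace = [state["ll"]]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = state["score"]
        # active set: components at the floor whose score pushes them
        # further out are frozen (boundary solution)
        at_floor = theta <= floor * (1.0 + 1e-8)
        free = ~(at_floor & (s < 0.0))
        if not free.any():
            converged = True
            break

        def em_delta():
            w, q = state["w"], state["q"]
            em_grad = np.array([
                q @ (w * q) - state["tr_PG"],
                q @ q - state["tr_PI"],
            ])
            return np.where(free, theta ** 2 * em_grad / n, 0.0)

        if it == 1:
            delta = em_delta()
        else:
            ai = state["ai"][np.ix_(free, free)]
            if np.linalg.cond(ai) > 1e12:
                if it == 2:  # structural: AI singular at the first AI step
                    raise ValueError(
                        "unidentifiable model: average-information matrix "
                        "is singular")
                delta = em_delta()  # near-boundary degeneracy: EM fallback
            else:
                delta = np.zeros(2)
                delta[free] = np.linalg.solve(ai, s[free])

        def try_step(step0):
            step = step0.copy()
            halved = 0
            for _ in range(25):
                cand = np.maximum(theta + step, floor)
                try:
                    cand_state = _uni_eval(cand, data)
                except ValueError:
                    step *= 0.5
                    halved += 1
                    continue
                if cand_state["ll"] >= state["ll"] - 1e-12:
                    return cand, cand_state, halved
                step *= 0.5
                halved += 1
            return None, None, halved

        new_theta, new_state, halved = try_step(delta)
        if new_state is None and it > 1:
            # AI direction failed: EM step is an ascent direction
            new_theta, new_state, halved = try_step(em_delta())
            halved = max(halved, 1)
        if new_state is None:
            converged = True
            break
        dll = new_state["ll"] - state["ll"]
        dtheta = np.abs(new_theta - theta).max() / max(vp, 1e-300)
        theta, state = new_theta, new_state
        trace.append(state["ll"])
        # halved steps signal the quadratic approximation is still poor;
        # only a full accepted step may declare convergence
        if it > 1 and halved == 0 and dll < tol and dtheta < tol:
            converged = True
            break

    ai = state["ai"]
    cov = np.linalg.pinv(ai) if np.linalg.cond(ai) > 1e12 else np.linalg.inv(ai)
    return VarianceComponents(
        sigma_u2=float(theta[0]), sigma_e2=float(theta[1]), cov=cov,
        loglik_reml=float(state["ll"]), n_iter=it, converged=converged,
        loglik_trace=trace)


# ---------------------------------------------------------------------------
# heritability and tests
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    p: float | None
    vc: VarianceComponents


def heritability(vc: VarianceComponents,
                 null_loglik: float | None = None) -> HeritabilityEstimate:
    """h2 = su2/(su2+se2) with delta-method SE and optional LRT p-value."""
    if not vc.converged:
        warnings.warn("heritability from a non-converged REML fit", RuntimeWarning,
                      stacklevel=2)
    total = vc.sigma_u2 + vc.sigma_e2
    if total <= 0:
        raise ValueError("zero total variance")
    h2 = vc.sigma_u2 / total
    grad = np.array([vc.sigma_e2, -vc.sigma_u2]) / total ** 2
    se = float(np.sqrt(grad @ vc.cov @ grad))
    p = lrt_pvalue(vc.loglik_reml, null_loglik) if null_loglik is not None else None
    return HeritabilityEstimate(h2=float(h2), se=se, p=p, vc=vc)


def lrt_pvalue(loglik_alt: float, loglik_null: float, tol: float = 1e-3) -> float:
    """Boundary likelihood-ratio p-value, null distribution 1/2 chi2_0 + 1/2 chi2_1."""
    lrt = 2.0 * (loglik_alt - loglik_null)
    if lrt < -tol:
        raise ValueError(
            f"alternative likelihood below null by {-lrt/2:.3g}: optimizer failure")
    lrt = max(lrt, 0.0)
    return float(0.5 * chi2.sf(lrt, df=1))


def profile_h2_argmax(data: MixedModelData, coarse: int = 101,
                      xtol: float = 1e-6):
    """Profile-likelihood h2 estimate on a grid plus local refinement.

    With V = Vtot [h2 G + (1-h2) I], the total variance profiles out in
    closed form (Vtot_hat = y'P_M y / (n-p)); the remaining 1-D profile
    over h2 is scanned on a coarse grid and refined by bounded scalar
    minimization.  Serves as an independent check on AI-REML.
    """
    w, _, yt, Xt = data.eig()
    n, p = data.n, data.p

    def neg_profile(h2: float) -> float:
        d = h2 * w + (1.0 - h2)
        if (d <= 0).any():
            return np.inf
        Wd = Xt / d[:, None]
        XtMX = Xt.T @ Wd
        sign, logdet = np.linalg.slogdet(XtMX)
        if sign <= 0:
            return np.inf
        q = yt / d - Wd @ np.linalg.solve(XtMX, Wd.T @ yt)
        ypy = float(yt @ q)
        vtot = ypy / (n - p)
        ll = -0.5 * ((n - p) * (np.log(vtot) + 1.0) + np.log(d).sum() + logdet)
        return -ll

    lo, hi = 1e-9, 1.0 - 1e-9
    grid = np.linspace(lo, hi, coarse)
    vals = np.array([neg_profile(h) for h in grid])
    i = int(vals.argmin())
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, coarse - 1)]
    res = scipy.optimize.minimize_scalar(
        neg_profile, bounds=(a, b), method="bounded",
        options={"xatol": xtol})
    return float(res.x), float(-res.fun)


# ---------------------------------------------------------------------------
# bivariate AI-REML
# ---------------------------------------------------------------------------

@dataclass
class BivariateFit:
    g11: float
    g12: float
    g22: float
    r11: float
    r12: float
    r22: float
    cov: np.ndarray            # 6x6 over (g11,g12,g22,r11,r12,r22)
    rg: float
    rg_se: float
    loglik_reml: float
    n_iter: int
    converged: bool
    boundary: bool = False
    loglik_trace: list = field(default_factory=list)

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.g11, self.g12, self.g22,
                         self.r11, self.r12, self.r22])


class _BivarEigModel:
    """Bivariate REML quantities when both traits share one sample and design.

    In the eigenbasis of G the stacked covariance is 2x2-block-diagonal
    per eigencomponent: C_i = Sg * w_i + Se.
    """

    E = {  # dV/dtheta within a 2x2 block
        "g11": np.array([[1.0, 0.0], [0.0, 0.0]]),
        "g12": np.array([[0.0, 1.0], [1.0, 0.0]]),
        "g22": np.array([[0.0, 0.0], [0.0, 1.0]]),
    }

    def __init__(self, data1: MixedModelData, y2):
        w, U, y1t, Xt = data1.eig()  # reuse the cached eigendecomposition
        self.w = w
        self.Y = np.column_stack([y1t, U.T @ y2])
        self.Xt = Xt
        self.n, self.p = data1.X.shape
        self.has_overlap = True

    def feasible(self, th) -> bool:
        g11, g12, g22, r11, r12, r22 = th
        a = g11 * self.w + r11
        c = g22 * self.w + r22
        b = g12 * self.w + r12
        return bool((a > 0).all() and (c > 0).all() and (a * c - b * b > 0).all())

    def evaluate(self, th):
        g11, g12, g22, r11, r12, r22 = th
        w, Y, Xt = self.w, self.Y, self.Xt
        n, p = self.n, self.p
        a = g11 * w + r11
        b = g12 * w + r12
        c = g22 * w + r22
        det = a * c - b * b
        Cinv = np.empty((n, 2, 2))
        Cinv[:, 0, 0] = c / det
        Cinv[:, 1, 1] = a / det
        Cinv[:, 0, 1] = Cinv[:, 1, 0] = -b / det

        def vinv(T):  # V^-1 applied to an n x 2 stack
            return np.einsum("ist,it->is", Cinv, T)

        # X' V^-1 X as a 2p x 2p block matrix
        XtVX = np.empty((2 * p, 2 * p))
        for t1 in range(2):
            for t2 in range(2):
                XtVX[t1 * p:(t1 + 1) * p, t2 * p:(t2 + 1) * p] = np.einsum(
                    "i,ij,ik->jk", Cinv[:, t1, t2], Xt, Xt)
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            raise ValueError("X' V^-1 X not positive definite")
        cf = scipy.linalg.cho_factor(XtVX)

        ViY = vinv(Y)
        rhs = np.concatenate([Xt.T @ ViY[:, 0], Xt.T @ ViY[:, 1]])
        beta = scipy.linalg.cho_solve(cf, rhs)
        Xb = np.column_stack([Xt @ beta[:p], Xt @ beta[p:]])
        Q = ViY - vinv(Xb)  # P y, n x 2
        ypy = float(np.sum(Y * Q))
        ll = -0.5 * (np.log(det).sum() + logdet_xvx + ypy)

        def apply_P(T):
            VT = vinv(T)
            rt = np.concatenate([Xt.T @ VT[:, 0], Xt.T @ VT[:, 1]])
            gam = scipy.linalg.cho_solve(cf, rt)
            Rg = np.column_stack([Xt @ gam[:p], Xt @ gam[p:]])
            return VT - vinv(Rg)

        scale = {"g11": w, "g12": w, "g22": w,
                 "r11": np.ones(n), "r12": np.ones(n), "r22": np.ones(n)}
        Ek = {k: self.E[k.replace("r", "g")] for k in PARAM_NAMES_BIVAR}

        U_list, trPA = [], []
        for k in PARAM_NAMES_BIVAR:
            s_i, E = scale[k], Ek[k]
            U_list.append((Q @ E) * s_i[:, None])
            # tr(V^-1 A) part
            if E[0, 1] == 0.0:
                t = int(E[0, 0] == 0.0)  # 0 for *11, 1 for *22
                tr_vinv_a = float((s_i * Cinv[:, t, t]).sum())
            else:
                tr_vinv_a = float((s_i * 2.0 * Cinv[:, 0, 1]).sum())
            # correction tr[(X'V^-1X)^-1 X'V^-1 A V^-1 X]
            D = np.einsum("ist,tu,iuv->isv", Cinv, E, Cinv)
            M = np.empty((2 * p, 2 * p))
            for t1 in range(2):
                for t2 in range(2):
                    M[t1 * p:(t1 + 1) * p, t2 * p:(t2 + 1) * p] = np.einsum(
                        "i,ij,ik->jk", s_i * D[:, t1, t2], Xt, Xt)
            trPA.append(tr_vinv_a - np.trace(scipy.linalg.cho_solve(cf, M)))

        PU = [apply_P(u) for u in U_list]
        k6 = len(PARAM_NAMES_BIVAR)
        ai = np.empty((k6, k6))
        score = np.empty(k6)
        for i in range(k6):
            score[i] = -0.5 * (trPA[i] - float(np.sum(Q * U_list[i])))
            for j in range(k6):
                ai[i, j] = 0.5 * float(np.sum(U_list[i] * PU[j]))
        ai = 0.5 * (ai + ai.T)
        return ll, score, ai


class _BivarDenseModel:
    """General bivariate REML with overlapping (not identical) samples."""

    def __init__(self, data1: MixedModelData, data2: MixedModelData, G: GRM):
        idx = {iid: i for i, iid in enumerate(G.ids)}
        i1 = np.array([idx[i] for i in data1.ids])
        i2 = np.array([idx[i] for i in data2.ids])
        self.G11 = G.values[np.ix_(i1, i1)]
        self.G12 = G.values[np.ix_(i1, i2)]
        self.G22 = G.values[np.ix_(i2, i2)]
        self.S12 = (np.asarray(data1.ids)[:, None]
                    == np.asarray(data2.ids)[None, :]).astype(float)
        self.has_overlap = bool(self.S12.any())
        self.y = np.concatenate([data1.y, data2.y])
        self.X = scipy.linalg.block_diag(data1.X, data2.X)
        _check_full_rank(self.X)
        self.n1, self.n2 = data1.n, data2.n

    def _blocks(self, k: str):
        n1, n2 = self.n1, self.n2
        Z12 = np.zeros((n1, n2))
        mats = {
            "g11": (self.G11, Z12, np.zeros((n2, n2))),
            "g12": (np.zeros((n1, n1)), self.G12, np.zeros((n2, n2))),
            "g22": (np.zeros((n1, n1)), Z12, self.G22),
            "r11": (np.eye(n1), Z12, np.zeros((n2, n2))),
            "r12": (np.zeros((n1, n1)), self.S12, np.zeros((n2, n2))),
            "r22": (np.zeros((n1, n1)), Z12, np.eye(n2)),
        }
        b11, b12, b22 = mats[k]
        return np.block([[b11, b12], [b12.T, b22]])

    def feasible(self, th) -> bool:
        V = self._V(th)
        try:
            scipy.linalg.cho_factor(V)
            return True
        except scipy.linalg.LinAlgError:
            return False

    def _V(self, th):
        g11, g12, g22, r11, r12, r22 = th
        n1, n2 = self.n1, self.n2
        return np.block([
            [g11 * self.G11 + r11 * np.eye(n1), g12 * self.G12 + r12 * self.S12],
            [(g12 * self.G12 + r12 * self.S12).T,
             g22 * self.G22 + r22 * np.eye(n2)],
        ])

    def evaluate(self, th):
        V = self._V(th)
        cf = scipy.linalg.cho_factor(V)
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        Vi = scipy.linalg.cho_solve(cf, np.eye(V.shape[0]))
        ViX = Vi @ self.X
        XtVX = self.X.T @ ViX
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            raise ValueError("X' V^-1 X not positive definite")
        P = Vi - ViX @ np.linalg.solve(XtVX, ViX.T)
        q = P @ self.y
        ll = -0.5 * (logdet_v + logdet_xvx + float(self.y @ q))

        A = [self._blocks(k) for k in PARAM_NAMES_BIVAR]
        U_list = [a @ q for a in A]
        PU = [P @ u for u in U_list]
        k6 = len(A)
        score = np.empty(k6)
        ai = np.empty((k6, k6))
        for i in range(k6):
            score[i] = -0.5 * (float(np.sum(P * A[i])) - float(q @ U_list[i]))
            for j in range(k6):
                ai[i, j] = 0.5 * float(U_list[i] @ PU[j])
        ai = 0.5 * (ai + ai.T)
        return ll, score, ai


def _clip_cov(c: float, v1: float, v2: float, frac: float = 0.95) -> float:
    bound = frac * np.sqrt(max(v1, 0.0) * max(v2, 0.0))
    return float(np.clip(c, -bound, bound))


def bivariate_ai_reml(data1: MixedModelData, data2: MixedModelData,
                      grm: GRM | None = None, init=None, tol: float = 1e-4,
                      max_iter: int = 100,
                      fixed: dict[str, float] | None = None) -> BivariateFit:
    """Bivariate AI-REML over theta = (g11, g12, g22, r11, r12, r22).

    Traits may be observed on overlapping individual sets; when the two
    sets (and designs) coincide, an eigendecomposition fast path is used.
    `fixed` pins named components (e.g. {"g12": 0.0, "r12": 0.0}).
    """
    same = (len(data1.ids) == len(data2.ids)
            and np.array_equal(np.asarray(data1.ids), np.asarray(data2.ids))
            and data1.X.shape == data2.X.shape
            and np.allclose(data1.X, data2.X))
    if same:
        model = _BivarEigModel(data1, data2.y)
    else:
        if grm is None:
            raise ValueError("a covering GRM is required for non-identical samples")
        model = _BivarDenseModel(data1, data2, grm)

    fixed = dict(fixed or {})
    if not model.has_overlap and "r12" not in fixed:
        warnings.warn("no overlapping individuals: residual covariance r12 "
                      "is not identifiable, fixing r12 = 0", RuntimeWarning,
                      stacklevel=2)
        fixed["r12"] = 0.0

    vp1 = float(np.var(data1.y, ddof=1))
    vp2 = float(np.var(data2.y, ddof=1))
    floor = _VAR_FLOOR_FRAC * np.array([vp1, 1.0, vp2, vp1, 1.0, vp2])

    if init is None:
        f1 = ai_reml_fit(data1, tol=tol, max_iter=max_iter)
        f2 = ai_reml_fit(data2, tol=tol, max_iter=max_iter)
        shared = pd.Index(data1.ids).intersection(pd.Index(data2.ids))
        if len(shared) >= 3:
            s1 = pd.Series(data1.y, index=data1.ids).loc[shared]
            s2 = pd.Series(data2.y, index=data2.ids).loc[shared]
            c = float(np.cov(s1, s2)[0, 1])
        else:
            c = 0.0
        theta = np.array([
            f1.sigma_u2, _clip_cov(0.5 * c, f1.sigma_u2, f2.sigma_u2),
            f2.sigma_u2,
            f1.sigma_e2, _clip_cov(0.5 * c, f1.sigma_e2, f2.sigma_e2),
            f2.sigma_e2,
        ])
    else:
        theta = np.asarray(init, dtype=float).copy()

    active = np.array([k not in fixed for k in PARAM_NAMES_BIVAR])
    for k, v in fixed.items():
        theta[PARAM_NAMES_BIVAR.index(k)] = v
    var_idx = np.array([0, 2, 3, 5])

    def project(th):
        th = th.copy()
        th[var_idx] = np.maximum(th[var_idx], floor[var_idx])
        return th

    theta = project(theta)
    if not model.feasible(theta):  # shrink covariances until V is PD
        for _ in range(60):
            theta[1] *= 0.5
            theta[4] *= 0.5
            if model.feasible(theta):
                break
        else:
            raise ValueError("could not find a feasible starting point")

    ll, score, ai = model.evaluate(theta)
    trace = [ll]
    converged = False
    vscale = max(vp1, vp2, 1e-300)
    it = 0
    for it in range(1, max_iter + 1):
        # freeze variance components pinned at the floor with outward score
        at_floor = np.zeros(6, dtype=bool)
        at_floor[var_idx] = theta[var_idx] <= floor[var_idx] * (1.0 + 1e-8)
        free = active & ~(at_floor & (score < 0.0))
        if not free.any():
            converged = True
            break
        ai_a = ai[np.ix_(free, free)]

        def try_step(step0, budget=12):
            step = step0.copy()
            halved = 0
            for _ in range(budget):
                cand = project(theta + step)
                if model.feasible(cand):
                    try:
                        cand_ll, cand_s, cand_ai = model.evaluate(cand)
                    except (ValueError, scipy.linalg.LinAlgError):
                        step *= 0.5
                        halved += 1
                        continue
                    if cand_ll >= ll - 1e-12:
                        return (cand, cand_ll, cand_s, cand_ai), halved
                step *= 0.5
                halved += 1
            return None, halved

        # Newton-type AI step; on ill-conditioning or failure, escalate a
        # Levenberg-Marquardt ridge (lam -> inf approaches a gradient step)
        dscale = np.abs(np.diag(ai_a))
        dscale[dscale <= 0] = dscale.max() if dscale.max() > 0 else 1.0
        new, halved = None, 0
        for lam in (0.0, 1e-8, 1e-6, 1e-4, 1e-2, 1.0, 1e2, 1e4):
            m_lm = ai_a + lam * np.diag(dscale)
            if np.linalg.cond(m_lm) > 1e12:
                continue
            delta = np.zeros(6)
            delta[free] = np.linalg.solve(m_lm, score[free])
            new, h = try_step(delta)
            halved = h if lam == 0.0 else max(h, 1)
            if new is not None:
                break
        if new is None:
            if it == 1:
                raise ValueError(
                    "unidentifiable model: average-information matrix "
                    "is singular")
            converged = True
            break
        cand, cand_ll, cand_s, cand_ai = new
        dll = cand_ll - ll
        dtheta = np.abs(cand - theta).max() / vscale
        theta, ll, score, ai = cand, cand_ll, cand_s, cand_ai
        trace.append(ll)
        if halved == 0 and dll < tol and dtheta < tol:
            converged = True
            break

    cov = np.zeros((6, 6))
    ai_a = ai[np.ix_(active, active)]
    cov_a = np.linalg.pinv(ai_a) if np.linalg.cond(ai_a) > 1e12 \
        else np.linalg.inv(ai_a)
    cov[np.ix_(active, active)] = cov_a

    g11, g12, g22, r11, r12, r22 = theta
    boundary = False
    denom = g11 * g22
    if denom <= 0:
        rg, rg_se, boundary = np.nan, np.nan, True
    else:
        rg = g12 / np.sqrt(denom)
        grad = np.zeros(6)
        grad[0] = -0.5 * rg / g11
        grad[1] = 1.0 / np.sqrt(denom)
        grad[2] = -0.5 * rg / g22
        rg_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        if abs(rg) > 1.0:
            boundary = True
            rg = float(np.sign(rg))
    return BivariateFit(
        g11=float(g11), g12=float(g12), g22=float(g22),
        r11=float(r11), r12=float(r12), r22=float(r22),
        cov=cov, rg=float(rg), rg_se=rg_se, loglik_reml=float(ll),
        n_iter=it, converged=converged, boundary=boundary, loglik_trace=trace)


# ---------------------------------------------------------------------------
# phenotypic correlation
# ---------------------------------------------------------------------------

def phenotypic_correlation(z1: pd.DataFrame, z2: pd.DataFrame) -> float:
    """Pearson correlation of two adjusted-phenotype tables over shared IDs."""
    merged = z1[["iid", "z"]].merge(z2[["iid", "z"]], on="iid",
                                    suffixes=("1", "2")).dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 shared individuals")
    a = merged["z1"].to_numpy()
    b = merged["z2"].to_numpy()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in adjusted phenotype")
    return float(np.corrcoef(a, b)[0, 1])
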