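"""Animal-model genetic-parameter estimation.

Relationship matrices: pedigree additive (A, tabular method), genomic
(G, VanRaden Z Z' / sum 2pq) and the single-step blend (H).  Variance
components are estimated by restricted maximum likelihood (REML) for the
animal model

    y = X b + a + e,   a ~ N(0, K sigma2_a),   e ~ N(0, I sigma2_e),

with K a relationship matrix over the phenotyped animals.  The univariate
fit profiles the likelihood on the variance ratio after a single
eigendecomposition of K, so each evaluation is O(n); the bivariate fit
uses the same rotation with unstructured 2x2 genetic and residual
covariances parameterized through Cholesky factors, giving heritabilities
and the genetic correlation with standard errors from the observed
information matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class RelationshipMatrix:
    kind: str  # 'A', 'G' or 'H'
    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")

    def subset(self, ids) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[a] for a in ids])
        return RelationshipMatrix(self.kind, list(ids), self.values[np.ix_(idx, idx)])


@dataclass
class VarianceEstimate:
    """REML variance components with derived ratios and their SEs."""

    sigma2_a: tuple
    sigma2_e: tuple
    h2: tuple
    loglik: float
    converged: bool
    n: int
    sigma_a12: float | None = None
    sigma_e12: float | None = None
    r_g: float | None = None
    se: dict = field(default_factory=dict)
    loglik_trace: list = field(default_factory=list)
    boundary: bool = False


# --------------------------------------------------------------------------
# relationship matrices
# --------------------------------------------------------------------------

def pedigree_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix by the tabular method.

    ``pedigree`` needs columns animal_id, sire_id, dam_id; unknown parents
    are blank/NaN and are treated as unrelated founders.  Parents absent
    from the animal column are added as founders.  Raises on pedigree
    cycles.
    """
    def norm(v):
        return "" if (pd.isna(v) or v == "") else str(v)

    anim = [str(a) for a in pedigree["animal_id"]]
    sire = [norm(s) for s in pedigree["sire_id"]]
    dam = [norm(d) for d in pedigree["dam_id"]]
    known = set(anim)
    extra = [p for p in dict.fromkeys(sire + dam) if p and p not in known]
    ids = extra + anim
    parents = {a: ("", "") for a in extra}
    parents.update({a: (s, d) for a, s, d in zip(anim, sire, dam)})

    # topological order (parents first); detects cycles
    order, state = [], {}

    def visit(a):
        stack = [(a, False)]
        while stack:
            node, done = stack.pop()
            if done:
                state[node] = 2
                order.append(node)
                continue
            st = state.get(node)
            if st == 1:
                raise ValueError("pedigree contains a cycle")
            if st == 2:
                continue
            state[node] = 1
            stack.append((node, True))
            for p in parents.get(node, ("", "")):
                if p:
                    stack.append((p, False))

    for a in ids:
        visit(a)
    pos = {a: i for i, a in enumerate(order)}
    m = len(order)
    A = np.zeros((m, m))
    for i, a in enumerate(order):
        s, d = parents.get(a, ("", ""))
        si = pos[s] if s else -1
        di = pos[d] if d else -1
        if i:
            row = np.zeros(i)
            if si >= 0:
                row += 0.5 * A[si, :i]
            if di >= 0:
                row += 0.5 * A[di, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    # return in the caller's id order (founders first as constructed)
    idx = np.array([pos[a] for a in ids])
    return RelationshipMatrix("A", ids, A[np.ix_(idx, idx)])


def vanraden_G(genotypes: pd.DataFrame) -> RelationshipMatrix:
    """Genomic relationship matrix G = Z Z' / sum(2 p q).

    ``genotypes``: animals x SNPs allele-dosage matrix in {0, 1, 2} with
    animal ids as the index.  Z = M - P where P holds twice the observed
    allele frequency; monomorphic SNPs are excluded.
    """
    M = genotypes.to_numpy(dtype=float)
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; G undefined")
    M = M[:, poly]
    p = p[poly]
    Z = M - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    G = Z @ Z.T / denom
    return RelationshipMatrix("G", [str(a) for a in genotypes.index], G)


def blend_H(
    A: RelationshipMatrix,
    G: RelationshipMatrix,
    weight: float = 0.95,
) -> RelationshipMatrix:
    """Single-step H matrix combining pedigree A with genomic G.

    G is first tuned (scaled and shifted) so its mean diagonal and mean
    element match the genotyped block A22, then blended as
    Gw = weight*G + (1-weight)*A22.  If the implied H is not positive
    semi-definite the pedigree share (1-weight) is increased with a
    warning.  Returned ids: non-genotyped animals first, then genotyped.
    """
    geno = set(G.ids)
    if not geno <= set(A.ids):
        raise ValueError("genotyped ids must be a subset of pedigree ids")
    if not geno:  # nobody genotyped: H degenerates to the pedigree matrix
        return RelationshipMatrix("H", list(A.ids), A.values.copy())
    others = [a for a in A.ids if a not in geno]
    order = others + list(G.ids)
    Ao = A.subset(order).values
    n1 = len(others)
    A11, A12, A22 = Ao[:n1, :n1], Ao[:n1, n1:], Ao[n1:, n1:]
    Gm = G.values

    # tune: alpha + beta*G matches A22 in mean diagonal and overall mean
    md_a, mn_a = float(np.mean(np.diag(A22))), float(np.mean(A22))
    md_g, mn_g = float(np.mean(np.diag(Gm))), float(np.mean(Gm))
    beta = (md_a - mn_a) / (md_g - mn_g) if abs(md_g - mn_g) > 1e-12 else 1.0
    alpha = mn_a - beta * mn_g
    Gt = alpha + beta * Gm

    w = weight
    while True:
        Gw = w * Gt + (1.0 - w) * A22
        if n1:
            A22inv = linalg.inv(A22)
            T = A12 @ A22inv
            H = np.block(
                [
                    [A11 + T @ (Gw - A22) @ A22inv @ A12.T, T @ Gw],
                    [(T @ Gw).T, Gw],
                ]
            )
        else:
            H = Gw
        if np.linalg.eigvalsh(H).min() > -1e-8 or w <= 0.05:
            break
        w -= 0.10
        warnings.warn(f"H not PSD; lowering genomic weight to {w:.2f}")
    return RelationshipMatrix("H", order, H)


# --------------------------------------------------------------------------
# design-matrix assembly
# --------------------------------------------------------------------------

def build_design(
    df: pd.DataFrame, factors=(), covariates=()
) -> np.ndarray:
    """Intercept + dummy-coded factors (reference level dropped) +
    covariates, with aliased columns removed by pivoted QR."""
    cols = [np.ones(len(df))]
    for f in factors:
        d = pd.get_dummies(df[f].astype(str), drop_first=True)
        cols.extend(d[c].to_numpy(dtype=float) for c in d.columns)
    for c in covariates:
        cols.append(df[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep = piv[diag > max(X.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 1)]
    return X[:, np.sort(keep)]


# --------------------------------------------------------------------------
# univariate REML
# --------------------------------------------------------------------------

def reml_univariate(
    phenotypes: pd.DataFrame,
    trait: str,
    relationship: RelationshipMatrix,
    fixed_factors=(),
    fixed_covariates=(),
) -> VarianceEstimate:
    """Univariate animal-model REML for one trait.

    Rows with a missing trait or covariate are dropped; the relationship
    matrix is subset to the remaining animals.
    """
    need = [trait, *fixed_covariates]
    d = phenotypes.dropna(subset=need)
    d = d[d["animal_id"].isin(set(relationship.ids))]
    y = d[trait].to_numpy(dtype=float)
    X = build_design(d, fixed_factors, fixed_covariates)
    K = relationship.subset(list(d["animal_id"])).values
    return reml_univariate_arrays(y, X, K)


def reml_univariate_arrays(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> VarianceEstimate:
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("not enough phenotyped animals for the model")
    Dv, U = linalg.eigh(K)
    Dv = np.maximum(Dv, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    def profile_lam(lam):
        w = lam * Dv + 1.0
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        cf = linalg.cho_factor(XtWX)
        beta = linalg.cho_solve(cf, Xw.T @ yt)
        r = yt - Xt @ beta
        ypy = float(r @ (r / w))
        s2e = ypy / (n - p)
        ll = -0.5 * (
            (n - p) * (_LOG2PI + 1.0 + math.log(s2e))
            + float(np.sum(np.log(w)))
            + 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        )
        return ll, s2e

    def profile(log_lam):
        return profile_lam(math.exp(log_lam))

    grid = np.linspace(-8.0, 8.0, 81)
    lls = np.array([profile(g)[0] for g in grid])
    trace = list(np.maximum.accumulate(lls))
    k = int(np.argmax(lls))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -profile(g)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    log_lam = float(res.x)
    ll, s2e = profile(log_lam)
    lam = math.exp(log_lam)
    # the additive variance may sit on its zero boundary, which the
    # log-ratio grid cannot reach; evaluate lambda = 0 exactly
    ll0, s2e0 = profile_lam(0.0)
    boundary = False
    if ll0 >= ll:
        lam, ll, s2e, boundary = 0.0, ll0, s2e0, True
    trace.append(max(ll, trace[-1]))
    s2a = lam * s2e
    h2 = s2a / (s2a + s2e)

    se = _uni_se(yt, Xt, Dv, n, p, s2a, s2e)
    return VarianceEstimate(
        sigma2_a=(s2a,),
        sigma2_e=(s2e,),
        h2=(h2,),
        loglik=ll,
        converged=True,
        n=n,
        se=se,
        loglik_trace=trace,
        boundary=boundary,
    )


def reml_loglik(y, X, K, s2a, s2e):
    """Restricted log-likelihood at given variance components.

    Shared by the fitter and by brute-force checks:
    -0.5 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py ].
    """
    n, p = X.shape
    V = s2a * K + s2e * np.eye(n)
    cf = linalg.cho_factor(V)
    Vi_y = linalg.cho_solve(cf, y)
    Vi_X = linalg.cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    cfx = linalg.cho_factor(XtViX)
    beta = linalg.cho_solve(cfx, X.T @ Vi_y)
    ypy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    ldV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ldX = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
    return -0.5 * ((n - p) * _LOG2PI + ldV + ldX + ypy)


def _uni_se(yt, Xt, Dv, n, p, s2a, s2e):
    def ll(th):
        a, e = th
        a = max(a, 0.0)  # boundary estimates: evaluate on the projection
        if e <= 0:
            return -np.inf
        w = a * Dv + e
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        sign, ldx = np.linalg.slogdet(XtWX)
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ beta
        ypy = float(r @ (r / w))
        return -0.5 * ((n - p) * _LOG2PI + float(np.sum(np.log(w))) + ldx + ypy)

    H = _num_hessian(ll, np.array([s2a, s2e]))
    se = {}
    try:
        C = linalg.inv(-H)
        if np.any(np.diag(C) < 0):
            raise linalg.LinAlgError
        se["sigma2_a"] = math.sqrt(C[0, 0])
        se["sigma2_e"] = math.sqrt(C[1, 1])
        tot = s2a + s2e
        g = np.array([s2e, -s2a]) / tot**2  # d h2 / d(s2a, s2e)
        se["h2"] = math.sqrt(max(float(g @ C @ g), 0.0))
    except linalg.LinAlgError:
        se = {"sigma2_a": float("nan"), "sigma2_e": float("nan"), "h2": float("nan")}
    return se


def _num_hessian(f, x0, rel_step=1e-4):
    k = len(x0)
    h = rel_step * (np.abs(x0) + rel_step)
    H = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


# --------------------------------------------------------------------------
# bivariate REML
# --------------------------------------------------------------------------

def reml_bivariate(
    phenotypes: pd.DataFrame,
    traits: tuple,
    relationship: RelationshipMatrix,
    fixed_factors=(),
    fixed_covariates=(),
) -> VarianceEstimate:
    """Bivariate animal model: unstructured 2x2 genetic and residual
    covariances, shared fixed effects, complete-case animals.

    Animals missing either trait are dropped so that the likelihood
    factorizes over the eigenbasis of the relationship matrix.  Returns
    heritabilities per trait and the genetic correlation
    r_g = sigma_a12 / sqrt(sigma2_a1 * sigma2_a2).
    """
    t1, t2 = traits
    need = [t1, t2, *fixed_covariates]
    d = phenotypes.dropna(subset=need)
    d = d[d["animal_id"].isin(set(relationship.ids))]
    Y = d[[t1, t2]].to_numpy(dtype=float)
    X = build_design(d, fixed_factors, fixed_covariates)
    K = relationship.subset(list(d["animal_id"])).values
    return reml_bivariate_arrays(Y, X, K)


def _chol2(theta3):
    l11, l21, l22 = math.exp(theta3[0]), theta3[1], math.exp(theta3[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


def _biv_loglik_cov(yt, Xt, Dv, G0, R0):
    """Restricted log-likelihood in the rotated basis.

    yt: n x 2, Xt: n x p, Dv: eigenvalues of K.  V is block-diagonal with
    2x2 blocks V_j = d_j G0 + R0.
    """
    n, p = Xt.shape
    v11 = Dv * G0[0, 0] + R0[0, 0]
    v12 = Dv * G0[0, 1] + R0[0, 1]
    v22 = Dv * G0[1, 1] + R0[1, 1]
    det = v11 * v22 - v12**2
    if np.any(det <= 0) or np.any(v11 <= 0):
        return None
    i11, i12, i22 = v22 / det, -v12 / det, v11 / det

    # 2p x 2p fixed-effect normal equations, trait-blocked
    XtVX = np.empty((2 * p, 2 * p))
    XtVX[:p, :p] = Xt.T @ (Xt * i11[:, None])
    XtVX[:p, p:] = Xt.T @ (Xt * i12[:, None])
    XtVX[p:, :p] = XtVX[:p, p:].T
    XtVX[p:, p:] = Xt.T @ (Xt * i22[:, None])
    w1 = i11 * yt[:, 0] + i12 * yt[:, 1]
    w2 = i12 * yt[:, 0] + i22 * yt[:, 1]
    XtVy = np.concatenate([Xt.T @ w1, Xt.T @ w2])
    try:
        cfx = linalg.cho_factor(XtVX)
    except linalg.LinAlgError:
        return None
    beta = linalg.cho_solve(cfx, XtVy)
    yVy = float(yt[:, 0] @ w1 + yt[:, 1] @ w2)
    ypy = yVy - float(XtVy @ beta)
    ldV = float(np.sum(np.log(det)))
    ldX = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
    N, P = 2 * n, 2 * p
    return -0.5 * ((N - P) * _LOG2PI + ldV + ldX + ypy)


def reml_bivariate_arrays(Y: np.ndarray, X: np.ndarray, K: np.ndarray) -> VarianceEstimate:
    n, p = X.shape
    Dv, U = linalg.eigh(K)
    Dv = np.maximum(Dv, 0.0)
    yt = U.T @ Y
    Xt = U.T @ X

    # start from univariate fits of each trait
    starts = []
    for t in range(2):
        est = reml_univariate_arrays(Y[:, t], X, K)
        starts.append((max(est.sigma2_a[0], 1e-4), max(est.sigma2_e[0], 1e-4)))

    theta0 = np.array(
        [
            0.5 * math.log(starts[0][0]), 0.0, 0.5 * math.log(starts[1][0]),
            0.5 * math.log(starts[0][1]), 0.0, 0.5 * math.log(starts[1][1]),
        ]
    )

    trace = []

    def nll(theta):
        G0 = _chol2(theta[:3])
        R0 = _chol2(theta[3:])
        ll = _biv_loglik_cov(yt, Xt, Dv, G0, R0)
        if ll is None or not np.isfinite(ll):
            return 1e12
        if not trace or ll > trace[-1]:
            trace.append(ll)
        return -ll

    res = optimize.minimize(
        nll, theta0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-10},
    )
    res2 = optimize.minimize(nll, res.x, method="BFGS", options={"maxiter": 200})
    theta = res2.x if res2.fun <= res.fun else res.x
    converged = bool(res.success or res2.success)

    G0 = _chol2(theta[:3])
    R0 = _chol2(theta[3:])
    ll = _biv_loglik_cov(yt, Xt, Dv, G0, R0)
    r_g = G0[0, 1] / math.sqrt(G0[0, 0] * G0[1, 1])
    h2 = tuple(G0[t, t] / (G0[t, t] + R0[t, t]) for t in range(2))

    # observed-information SEs on the covariance scale
    def ll_cov(v):
        Gm = np.array([[v[0], v[1]], [v[1], v[2]]])
        Rm = np.array([[v[3], v[4]], [v[4], v[5]]])
        out = _biv_loglik_cov(yt, Xt, Dv, Gm, Rm)
        return -np.inf if out is None else out

    v0 = np.array([G0[0, 0], G0[0, 1], G0[1, 1], R0[0, 0], R0[0, 1], R0[1, 1]])
    se = {}
    try:
        H = _num_hessian(ll_cov, v0)
        C = linalg.inv(-H)
        if np.any(np.diag(C) < 0):
            raise linalg.LinAlgError
        g11, g12, g22 = v0[0], v0[1], v0[2]
        gr = np.zeros(6)
        gr[0] = -0.5 * r_g / g11
        gr[1] = 1.0 / math.sqrt(g11 * g22)
        gr[2] = -0.5 * r_g / g22
        se["r_g"] = math.sqrt(max(float(gr @ C @ gr), 0.0))
        for t, (gi, ri) in enumerate(((0, 3), (2, 5))):
            tot = v0[gi] + v0[ri]
            gh = np.zeros(6)
            gh[gi] = v0[ri] / tot**2
            gh[ri] = -v0[gi] / tot**2
            se[f"h2_{t + 1}"] = math.sqrt(max(float(gh @ C @ gh), 0.0))
    except (linalg.LinAlgError, ValueError):  # singular/boundary information
        se = {"r_g": float("nan"), "h2_1": float("nan"), "h2_2": float("nan")}
    # a near-singular information matrix yields astronomically large SEs;
    # report those as not estimable
    se = {k: (v if np.isfinite(v) and v < 1e3 else float("nan")) for k, v in se.items()}

    return VarianceEstimate(
        sigma2_a=(G0[0, 0], G0[1, 1]),
        sigma2_e=(R0[0, 0], R0[1, 1]),
        sigma_a12=float(G0[0, 1]),
        sigma_e12=float(R0[0, 1]),
        h2=h2,
        r_g=float(r_g),
        loglik=float(ll),
        converged=converged,
        n=n,
        se=se,
        loglik_trace=trace,
    )
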