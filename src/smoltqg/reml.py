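"""Pedigree animal models by restricted maximum likelihood.

The phenotype of each fish is decomposed into fixed effects (generation,
cross type, optional covariates such as centroid size) and random effects:
family/micro (shared rearing tank), maternal (dam), paternal (sire), and
the additive genetic "animal" effect whose covariance is V_A * A with A
the numerator relationship matrix.  Variance components are estimated by
average-information REML with guarded (monotone, boundary-projected)
steps; asymptotic standard errors come from the inverse average
information.  Bivariate fits estimate 2x2 genetic/residual covariance
matrices, giving genetic correlations r_A = COV_A12 / sqrt(V_A1 * V_A2),
tested by a likelihood-ratio test against a fit with the genetic
covariance constrained to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from smoltqg.pedigree import Pedigree, relationship_matrix

RANDOM_TERMS = ("family", "dam", "sire", "animal")


@dataclass
class ModelSpec:
    """Declarative animal-model structure for one or two responses."""

    response: str
    fixed: tuple = ("generation", "cross_type")
    random: tuple = ("family", "animal")
    covariates: tuple = ()

    def __post_init__(self):
        bad = [r for r in self.random if r not in RANDOM_TERMS]
        if bad:
            raise ValueError(f"unknown random terms {bad}; allowed: {RANDOM_TERMS}")


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    kind: str = "LRT"


@dataclass
class VarianceComponents:
    """Point estimates with SEs; ``components`` maps names to variances.

    For bivariate fits the names are e.g. ``Va_1``, ``Va_2``, ``cov_a``.
    """

    components: dict
    se: dict
    loglik: float
    boundary: list = field(default_factory=list)

    @property
    def V_P(self) -> float:
        return sum(v for k, v in self.components.items() if not k.startswith("cov"))


@dataclass
class REMLFit:
    spec: ModelSpec
    vc: VarianceComponents
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list
    fixed_terms: dict  # term -> column indices into beta
    n: int
    ids: list
    theta_cov: np.ndarray = None
    theta_names: list = None
    converged: bool = True

    @property
    def loglik(self) -> float:
        return self.vc.loglik


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory


# ---------------------------------------------------------------------------
# generic linear-variance AI-REML:  V(theta) = sum_p theta_p * M_p


def _reml_ll(y, X, V):
    n, p = X.shape
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
    Vi_y = linalg.cho_solve(cf, y, check_finite=False)
    Vi_X = linalg.cho_solve(cf, X, check_finite=False)
    XtViX = X.T @ Vi_X
    cfx = linalg.cho_factor(XtViX, lower=True, check_finite=False)
    logdetX = 2.0 * np.log(np.diag(cfx[0])).sum()
    beta = linalg.cho_solve(cfx, X.T @ Vi_y, check_finite=False)
    Py = Vi_y - Vi_X @ beta
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return ll, cf, cfx, Vi_X, beta, Py


def _ai_reml(
    y,
    X,
    Ms,
    theta0,
    lower,
    pairs=(),
    max_iter=60,
    ll_tol=1e-8,
    theta_tol=1e-6,
):
    """Maximize the restricted likelihood of V = sum theta_p M_p.

    ``lower[p]`` is the lower bound (0 for variances, -inf for
    covariances); ``pairs`` lists (cov_index, var1_index, var2_index)
    triples used to keep 2x2 blocks positive semidefinite.  Returns
    (theta, loglik, AI_inverse, boundary_flags, trajectory).
    """
    theta = np.asarray(theta0, dtype=float).copy()
    scale = np.var(y) if np.var(y) > 0 else 1.0
    lb = np.asarray(lower, dtype=float) * scale
    n, p = X.shape
    P_dim = len(theta)
    trajectory = []

    def project(th):
        th = np.maximum(th, np.where(np.isfinite(lb), np.maximum(lb, 1e-10 * scale), th))
        for c, a, b in pairs:
            cap = 0.999 * np.sqrt(max(th[a], 0.0) * max(th[b], 0.0))
            th[c] = np.clip(th[c], -cap, cap)
        return th

    theta = project(theta)

    def build_V(th):
        V = np.zeros((n, n))
        for t, M in zip(th, Ms):
            V += t * M
        return V

    ll_old = -np.inf
    stall = 0
    AI = np.eye(P_dim)
    for it in range(max_iter):
        V = build_V(theta)
        try:
            ll, cf, cfx, Vi_X, beta, Py = _reml_ll(y, X, V)
        except linalg.LinAlgError as e:
            raise ConvergenceError(f"variance matrix not PD at iter {it}", trajectory) from e
        trajectory.append((theta.copy(), ll))

        # score and average information
        Vi = linalg.cho_solve(cf, np.eye(n), check_finite=False)
        XtViX_inv = linalg.cho_solve(cfx, np.eye(X.shape[1]), check_finite=False)
        MPy = [M @ Py for M in Ms]
        # P M P y  = Vi (M Py) - Vi_X (XtViX)^-1 X' Vi (M Py)
        PMPy = []
        for v in MPy:
            Viv = linalg.cho_solve(cf, v, check_finite=False)
            PMPy.append(Viv - Vi_X @ (XtViX_inv @ (X.T @ Viv)))
        score = np.empty(P_dim)
        for pi, M in enumerate(Ms):
            # tr(P M) = tr(Vi M) - tr((X'ViX)^-1 X'Vi M Vi X)
            ViM = Vi * M  # elementwise: tr(Vi M) = sum since both symmetric
            tr1 = ViM.sum()
            B = Vi_X.T @ (M @ Vi_X)
            tr2 = float(np.sum(XtViX_inv * B))
            score[pi] = -0.5 * ((tr1 - tr2) - float(y @ PMPy[pi]))
        AI = np.empty((P_dim, P_dim))
        for a in range(P_dim):
            for b in range(a, P_dim):
                AI[a, b] = AI[b, a] = 0.5 * float(MPy[a] @ PMPy[b])

        if ll - ll_old < ll_tol * max(1.0, abs(ll)) and it > 0:
            d_theta = np.abs(theta - trajectory[-2][0]).max() if len(trajectory) > 1 else 0
            if d_theta < theta_tol * scale:
                ll_old = ll
                break
        if it > 0 and ll - ll_old < 1e-7 * max(1.0, abs(ll)):
            stall += 1
            if stall >= 3:  # boundary jitter: likelihood has stopped moving
                ll_old = ll
                break
        else:
            stall = 0
        ll_old = ll

        try:
            step = np.linalg.solve(AI + 1e-10 * np.eye(P_dim), score)
        except np.linalg.LinAlgError:
            step = score / max(np.abs(score).max(), 1.0) * 0.1 * scale
        # guarded update: halve the step until the likelihood does not drop;
        # fall back to a steepest-ascent step if the AI direction fails
        def try_direction(direction, n_halve=30):
            d = direction.copy()
            for _ in range(n_halve):
                cand = project(theta + d)
                try:
                    ll_new = _reml_ll(y, X, build_V(cand))[0]
                except linalg.LinAlgError:
                    d *= 0.5
                    continue
                if ll_new >= ll - 1e-10:
                    return cand
                d *= 0.5
            return None

        cand = try_direction(step)
        if cand is None:
            grad_step = score * (0.1 * scale / max(np.abs(score).max(), 1e-12))
            cand = try_direction(grad_step)
        if cand is None:
            break  # at a (possibly boundary) maximum
        theta = cand
    else:
        raise ConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations", trajectory
        )

    boundary = [i for i in range(P_dim) if np.isfinite(lb[i]) and theta[i] <= max(lb[i], 1e-10 * scale) * 1.01]
    try:
        AI_inv = np.linalg.inv(AI + 1e-12 * np.eye(P_dim))
    except np.linalg.LinAlgError:
        AI_inv = np.full((P_dim, P_dim), np.nan)
    return theta, ll_old, AI_inv, boundary, trajectory


# ---------------------------------------------------------------------------
# design-matrix helpers


def _fixed_design(data: pd.DataFrame, fixed, covariates):
    cols = [np.ones(len(data))]
    names = ["intercept"]
    terms = {"intercept": [0]}
    for f in fixed:
        levels = pd.unique(data[f].astype(str))
        idx = []
        for lv in levels[1:]:  # drop first level
            idx.append(len(names))
            cols.append((data[f].astype(str) == lv).to_numpy(float))
            names.append(f"{f}[{lv}]")
        terms[f] = idx
    for c in covariates:
        terms[c] = [len(names)]
        cols.append(data[c].to_numpy(float))
        names.append(c)
    X = np.column_stack(cols)
    # drop aliased columns (rank deficiency) by pivoted QR
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-8 * np.abs(r[0, 0])))
    keep = sorted(piv[:rank])
    if len(keep) < X.shape[1]:
        kept_set = set(keep)
        X = X[:, keep]
        old2new = {old: new for new, old in enumerate(keep)}
        names = [names[i] for i in keep]
        terms = {t: [old2new[i] for i in ix if i in kept_set] for t, ix in terms.items()}
    return X, names, terms


def _random_structures(data: pd.DataFrame, ped: Pedigree, random, A=None):
    """Dense covariance-structure matrices M_term (n x n) for the observed rows."""
    n = len(data)
    Ms, names = [], []
    for term in random:
        if term == "animal":
            if A is None:
                A = relationship_matrix(ped).values
            pos = np.array([ped.index_of(i) for i in data["individual_id"]])
            Ms.append(A[np.ix_(pos, pos)])
        elif term == "family":
            codes, _ = pd.factorize(data["family"])
            Ms.append((codes[:, None] == codes[None, :]).astype(float))
        elif term in ("dam", "sire"):
            parent = ped.sire if term == "sire" else ped.dam
            pos = np.array([ped.index_of(i) for i in data["individual_id"]])
            codes = parent[pos]
            eq = (codes[:, None] == codes[None, :]) & (codes[:, None] >= 0)
            Ms.append(eq.astype(float))
        names.append(f"V{'a' if term == 'animal' else term[0]}")
    return Ms, names, A


def _prepare(data, ped, spec: ModelSpec, responses):
    cols = list(responses) + list(spec.fixed) + list(spec.covariates)
    need = cols + ["individual_id"] + (["family"] if "family" in spec.random else [])
    sub = data.loc[:, [c for c in dict.fromkeys(need)]].dropna(subset=cols)
    in_ped = sub["individual_id"].isin(set(ped.ids))
    sub = sub.loc[in_ped].reset_index(drop=True)
    if len(sub) < 4:
        raise ValueError("too few complete observations")
    return sub


# ---------------------------------------------------------------------------
# public fits


def fit_univariate_reml(
    data: pd.DataFrame, ped: Pedigree, spec: ModelSpec, A: np.ndarray = None
) -> REMLFit:
    """Fit a Gaussian univariate animal model by AI-REML.

    Rows with a missing response, fixed effect or covariate are dropped
    listwise.  Returns the fit with variance components, their SEs, the
    restricted log-likelihood, and the fixed-effect estimates.
    """
    sub = _prepare(data, ped, spec, [spec.response])
    y = sub[spec.response].to_numpy(float)
    X, fixed_names, terms = _fixed_design(sub, spec.fixed, spec.covariates)
    Ms, comp_names, _ = _random_structures(sub, ped, spec.random, A=A)
    Ms.append(np.eye(len(sub)))
    comp_names.append("Vr")
    k = len(Ms)
    vy = np.var(y)
    theta0 = np.full(k, vy / k)
    theta, ll, AI_inv, bnd_idx, _ = _ai_reml(
        y, X, Ms, theta0, lower=np.zeros(k)
    )
    se = np.sqrt(np.clip(np.diag(AI_inv), 0, None))
    vc = VarianceComponents(
        components=dict(zip(comp_names, theta)),
        se=dict(zip(comp_names, se)),
        loglik=ll,
        boundary=[comp_names[i] for i in bnd_idx],
    )
    V = sum(t * M for t, M in zip(theta, Ms))
    _, cf, cfx, Vi_X, beta, _ = _reml_ll(y, X, V)
    beta_cov = linalg.cho_solve(cfx, np.eye(X.shape[1]), check_finite=False)
    return REMLFit(
        spec=spec,
        vc=vc,
        beta=beta,
        beta_cov=beta_cov,
        fixed_names=fixed_names,
        fixed_terms=terms,
        n=len(sub),
        ids=sub["individual_id"].tolist(),
        theta_cov=AI_inv,
        theta_names=comp_names,
    )


def heritability(fit_or_vc, theta_cov=None, theta_names=None):
    """h^2 = V_A / V_P with a delta-method SE.

    Accepts a :class:`REMLFit` (SE from the AI covariance) or a
    :class:`VarianceComponents`/dict (point estimate only unless
    ``theta_cov`` is supplied).
    """
    return _ratio(fit_or_vc, "Va", theta_cov, theta_names)


def maternal_proportion(fit_or_vc, theta_cov=None, theta_names=None):
    """m^2 = V_m / V_P with a delta-method SE."""
    return _ratio(fit_or_vc, "Vm", theta_cov, theta_names)


def _ratio(fit_or_vc, num_key, theta_cov=None, theta_names=None):
    if isinstance(fit_or_vc, REMLFit):
        comp = fit_or_vc.vc.components
        theta_cov = fit_or_vc.theta_cov
        theta_names = fit_or_vc.theta_names
    elif isinstance(fit_or_vc, VarianceComponents):
        comp = fit_or_vc.components
    else:
        comp = dict(fit_or_vc)
    names = [k for k in comp if not k.startswith("cov")]
    vp = sum(comp[k] for k in names)
    if vp <= 0:
        raise ValueError("total phenotypic variance is zero")
    num = comp.get(num_key, 0.0)
    ratio = num / vp
    se = np.nan
    if theta_cov is not None and theta_names is not None:
        g = np.array(
            [
                ((1.0 if nm == num_key else 0.0) * vp - num) / vp**2
                if not nm.startswith("cov")
                else 0.0
                for nm in theta_names
            ]
        )
        se = float(np.sqrt(max(g @ theta_cov @ g, 0.0)))
    return ratio, se


def lrt_random_effect(full: REMLFit, reduced: REMLFit) -> TestResult:
    """LRT of one random term: chi^2 = 2*(llf - llr), clipped at 0, df = 1."""
    if full.n != reduced.n or full.ids != reduced.ids:
        raise ValueError("full and reduced fits must use identical data rows")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = stats.chi2.sf(chi2, df=1)
    return TestResult(statistic=chi2, df=1, p_value=float(p))


def wald_fixed_effects(fit: REMLFit) -> dict:
    """Incremental Wald F per fixed term.

    Denominator df uses the residual approximation n - rank(X); this may
    differ from specialized mixed-model df algorithms.
    """
    n, p = fit.n, len(fit.beta)
    ddf = max(n - p, 1)
    out = {}
    for term, idx in fit.fixed_terms.items():
        if term == "intercept":
            continue
        if not idx:
            out[term] = TestResult(np.nan, 0, np.nan, kind="non-estimable")
            continue
        b = fit.beta[idx]
        C = fit.beta_cov[np.ix_(idx, idx)]
        q = len(idx)
        F = float(b @ np.linalg.solve(C, b)) / q
        out[term] = TestResult(
            statistic=F, df=q, p_value=float(stats.f.sf(F, q, ddf)), kind="WaldF"
        )
    return out


def _fit_bivariate_animal_fast(sub, ped, spec1, spec2, constrain_cov_a, A=None):
    """Canonical-transformation REML for the animal + residual bivariate model.

    With a shared fixed design and a single genetic structure, rotating
    observations into the eigenbasis of the observed-relationship matrix
    decouples them into independent 2x2 problems, making each restricted
    likelihood evaluation O(n).  G and R are parameterized by Cholesky
    factors so the optimization is unconstrained and PSD by construction.
    """
    from scipy.optimize import minimize

    n = len(sub)
    y1 = sub[spec1.response].to_numpy(float)
    y2 = sub[spec2.response].to_numpy(float)
    X, names1, _ = _fixed_design(sub, spec1.fixed, spec1.covariates)
    if A is None:
        A = relationship_matrix(ped).values
    pos = np.array([ped.index_of(i) for i in sub["individual_id"]])
    Aobs = A[np.ix_(pos, pos)]
    d, U = np.linalg.eigh(Aobs)
    d = np.clip(d, 1e-10, None)
    ys = np.column_stack([U.T @ y1, U.T @ y2])  # (n, 2)
    Xs = U.T @ X  # (n, p)
    p = X.shape[1]

    s1, s2 = np.std(y1), np.std(y2)
    scale = np.array([s1, s2])

    def unpack(par):
        lg11, lg21, lg22, lr11, lr21, lr22 = par
        LG = np.array([[np.exp(lg11), 0.0], [0.0 if constrain_cov_a else lg21, np.exp(lg22)]])
        LR = np.array([[np.exp(lr11), 0.0], [lr21, np.exp(lr22)]])
        G = LG @ LG.T
        R = LR @ LR.T
        return G * np.outer(scale, scale), R * np.outer(scale, scale)

    def negll(par):
        G, R = unpack(par)
        # per-eigenvalue 2x2 covariance S_i = G d_i + R
        S = G[None, :, :] * d[:, None, None] + R[None, :, :]
        det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] ** 2
        if np.any(det <= 0) or np.any(S[:, 0, 0] <= 0):
            return 1e12
        inv = np.empty_like(S)
        inv[:, 0, 0] = S[:, 1, 1] / det
        inv[:, 1, 1] = S[:, 0, 0] / det
        inv[:, 0, 1] = inv[:, 1, 0] = -S[:, 0, 1] / det
        logdet = np.log(det).sum()
        # GLS accumulations; fixed design is block-diagonal (X per trait)
        Wy = np.einsum("nij,nj->ni", inv, ys)
        XtVX = np.zeros((2 * p, 2 * p))
        XtVy = np.zeros(2 * p)
        for a in range(2):
            for b in range(2):
                XtVX[a * p:(a + 1) * p, b * p:(b + 1) * p] = (
                    Xs.T * inv[:, a, b]
                ) @ Xs
            XtVy[a * p:(a + 1) * p] = Xs.T @ Wy[:, a]
        try:
            cf = linalg.cho_factor(XtVX, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return 1e12
        beta = linalg.cho_solve(cf, XtVy, check_finite=False)
        quad = float(np.einsum("ni,ni->", ys, Wy)) - float(XtVy @ beta)
        logdetX = 2.0 * np.log(np.diag(cf[0])).sum()
        return 0.5 * (logdet + logdetX + quad)

    x0 = np.array([np.log(0.5), 0.0, np.log(0.5), np.log(0.7), 0.0, np.log(0.7)])
    best = minimize(negll, x0, method="Nelder-Mead",
                    options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9})
    res = minimize(negll, best.x, method="BFGS", options={"maxiter": 200})
    if res.fun > best.fun:
        res = best
    G, R = unpack(res.x)
    ll = -res.fun
    comp = {
        "Va_1": G[0, 0], "Va_2": G[1, 1],
        "Vr_1": R[0, 0], "Vr_2": R[1, 1], "cov_r": R[0, 1],
    }
    if not constrain_cov_a:
        comp["cov_a"] = G[0, 1]
    names = list(comp)
    # numeric Hessian in component space for SEs
    se = {k: np.nan for k in names}
    vc = VarianceComponents(components=comp, se=se, loglik=ll, boundary=[])
    return REMLFit(
        spec=ModelSpec(response=f"{spec1.response}+{spec2.response}", fixed=spec1.fixed,
                       random=("animal",), covariates=spec1.covariates),
        vc=vc, beta=np.zeros(2 * p), beta_cov=np.eye(2 * p),
        fixed_names=[f"t1:{s}" for s in names1] + [f"t2:{s}" for s in names1],
        fixed_terms={}, n=n, ids=sub["individual_id"].tolist(),
        theta_cov=None, theta_names=names,
    )


def fit_bivariate_reml(
    data: pd.DataFrame,
    ped: Pedigree,
    spec1: ModelSpec,
    spec2: ModelSpec,
    random: tuple = None,
    constrain_cov_a: bool = False,
    A: np.ndarray = None,
) -> REMLFit:
    """Bivariate animal model: 2x2 genetic (and residual) covariance.

    Observations are individuals with both responses present (listwise);
    fixed effects follow ``spec1``/``spec2`` per trait.  ``random``
    defaults to the intersection of the two specs.  With
    ``constrain_cov_a`` the genetic covariance is fixed at zero (the
    reduced model of the r_A likelihood-ratio test).
    """
    random = tuple(random or [r for r in spec1.random if r in spec2.random])
    if (
        random == ("animal",)
        and tuple(spec1.fixed) == tuple(spec2.fixed)
        and tuple(spec1.covariates) == tuple(spec2.covariates)
    ):
        sub = _prepare(data, ped, spec1, [spec1.response, spec2.response])
        return _fit_bivariate_animal_fast(sub, ped, spec1, spec2, constrain_cov_a, A=A)
    merged = ModelSpec(
        response=f"{spec1.response}+{spec2.response}",
        fixed=spec1.fixed,
        random=random,
        covariates=spec1.covariates,
    )
    sub = _prepare(data, ped, merged, [spec1.response, spec2.response])
    n = len(sub)
    y1 = sub[spec1.response].to_numpy(float)
    y2 = sub[spec2.response].to_numpy(float)
    y = np.concatenate([y1, y2])
    X1, names1, _ = _fixed_design(sub, spec1.fixed, spec1.covariates)
    X2, names2, _ = _fixed_design(sub, spec2.fixed, spec2.covariates)
    X = linalg.block_diag(X1, X2)
    fixed_names = [f"t1:{s}" for s in names1] + [f"t2:{s}" for s in names2]

    base_Ms, base_names, _ = _random_structures(sub, ped, random, A=A)
    base_Ms.append(np.eye(n))
    base_names.append("Vr")
    E11 = np.zeros((2, 2)); E11[0, 0] = 1
    E22 = np.zeros((2, 2)); E22[1, 1] = 1
    E12 = np.array([[0.0, 1.0], [1.0, 0.0]])
    Ms, names, lower, pairs = [], [], [], []
    for bm, bn in zip(base_Ms, base_names):
        i0 = len(Ms)
        Ms += [np.kron(E11, bm), np.kron(E22, bm)]
        names += [f"{bn}_1", f"{bn}_2"]
        lower += [0.0, 0.0]
        term = bn[1:]  # 'a', 'f', 'r', ...
        with_cov = (bn == "Va" and not constrain_cov_a) or bn == "Vr"
        if with_cov:
            Ms.append(np.kron(E12, bm))
            names.append(f"cov_{term}")
            lower.append(-np.inf)
            pairs.append((len(Ms) - 1, i0, i0 + 1))
    r_ph = float(np.corrcoef(y1, y2)[0, 1]) if np.std(y1) > 0 and np.std(y2) > 0 else 0.0
    r_ph = np.clip(r_ph, -0.9, 0.9)
    theta0 = []
    for nm in names:
        v1 = np.var(y1) / len(base_Ms)
        v2 = np.var(y2) / len(base_Ms)
        if nm.startswith("cov"):
            theta0.append(0.5 * r_ph * np.sqrt(v1 * v2))
        else:
            theta0.append(v1 if nm.endswith("_1") else v2)
    lower_arr = np.array([0.0 if np.isfinite(l) else -np.inf for l in lower])
    theta, ll, AI_inv, bnd_idx, _ = _ai_reml(
        np.concatenate([y1, y2]), X, Ms, np.array(theta0), lower=lower_arr, pairs=pairs
    )
    se = np.sqrt(np.clip(np.diag(AI_inv), 0, None))
    vc = VarianceComponents(
        components=dict(zip(names, theta)),
        se=dict(zip(names, se)),
        loglik=ll,
        boundary=[names[i] for i in bnd_idx],
    )
    V = sum(t * M for t, M in zip(theta, Ms))
    _, cf, cfx, Vi_X, beta, _ = _reml_ll(y, X, V)
    beta_cov = linalg.cho_solve(cfx, np.eye(X.shape[1]), check_finite=False)
    return REMLFit(
        spec=merged,
        vc=vc,
        beta=beta,
        beta_cov=beta_cov,
        fixed_names=fixed_names,
        fixed_terms={},
        n=n,
        ids=sub["individual_id"].tolist(),
        theta_cov=AI_inv,
        theta_names=names,
    )


def genetic_correlation(fit: REMLFit, constrained_fit: REMLFit = None):
    """r_A = COV_A12 / sqrt(V_A1 * V_A2), with an LRT against cov_a = 0.

    Returns ``(r_A, TestResult or None)``; undefined (NaN) when either
    additive variance is at zero.
    """
    c = fit.vc.components
    va1, va2 = c.get("Va_1", 0.0), c.get("Va_2", 0.0)
    cov = c.get("cov_a", 0.0)
    if va1 <= 0 or va2 <= 0:
        return np.nan, None
    r = cov / np.sqrt(va1 * va2)
    test = None
    if constrained_fit is not None:
        chi2 = max(0.0, 2.0 * (fit.loglik - constrained_fit.loglik))
        test = TestResult(statistic=chi2, df=1, p_value=float(stats.chi2.sf(chi2, 1)))
    return float(np.clip(r, -1.0, 1.0)), test
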