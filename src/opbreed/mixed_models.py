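"""Individual-tree mixed models: stage-1 adjustment, EM-REML(+AI), MME, BLUP.

Two model families are supported, both multi-site "site-as-correlated-trait"
individual-tree models:

* single-trait multi-site — response keys are (trait, site_1..S); the
  additive effects follow a ~ N(0, Σ_a ⊗ K) with an unstructured S×S
  genetic (co)variance Σ_a and any relationship matrix K (A for ABLUP,
  G for GBLUP, plus D and G∘D terms for the ADE variant);
* multi-trait multi-site — keys are all trait×site combinations with an
  unstructured (T·S)×(T·S) genetic (co)variance.

Residuals are unstructured across traits within a site and structurally
zero across sites (each tree grows on one site, sites are assessed
separately).  Variance components are estimated by EM-REML iterated to a
relative log-likelihood tolerance, followed by one Average-Information
round whose inverse provides standard errors.  The restricted likelihood
is evaluated in observation space with a Cholesky factorisation per
iteration; Henderson's mixed-model equations are assembled separately for
BLUP solutions and prediction-error variances (the diagonal of the inverse
coefficient matrix), and the two routes are cross-checked in the tests.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .io import PedigreeTable, PhenotypeTable, ValidationError
from .relmat import RelationshipMatrix, build_A

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "MMESystem",
    "BreedingValueSet",
    "adjust_stage1",
    "fit_reml",
    "assemble_mme",
    "predict_blup",
    "fit_model",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ModelSpec:
    """Which (trait, site) responses to model and with which random terms.

    ``random_terms`` maps a term name ('additive', 'dominance', 'epistatic')
    to its relationship matrix; each term gets an unstructured covariance
    across all response keys.
    """

    traits: list[str]
    sites: list[str]
    random_terms: list[tuple[str, RelationshipMatrix]]
    label: str = "GBLUP-A"

    def __post_init__(self):
        if not self.traits or not self.sites:
            raise ValidationError("ModelSpec needs at least one trait and one site")
        if not self.random_terms:
            raise ValidationError("ModelSpec needs at least one random term")

    @property
    def keys(self) -> list[tuple[str, str]]:
        return [(t, s) for t in self.traits for s in self.sites]

    @property
    def q(self) -> int:
        return len(self.keys)


@dataclasses.dataclass
class VarianceComponents:
    keys: list[tuple[str, str]]
    sigma: dict  # term name -> (q, q) covariance across keys
    residual: dict  # site -> (traits_at_site list, matrix)
    param_labels: list = None
    cov_params: np.ndarray | None = None
    se: dict | None = None
    loglik_trace: list = dataclasses.field(default_factory=list)
    converged: bool = False
    n_iterations: int = 0

    def residual_key_matrix(self) -> np.ndarray:
        """Residual covariance on the key grid (zero across sites)."""
        q = len(self.keys)
        R = np.zeros((q, q))
        for a, (ta, sa) in enumerate(self.keys):
            for b, (tb, sb) in enumerate(self.keys):
                if sa != sb:
                    continue
                traits, mat = self.residual[sa]
                if ta in traits and tb in traits:
                    R[a, b] = mat[traits.index(ta), traits.index(tb)]
        return R

    def genetic_variance(self, term: str, key: tuple[str, str]) -> float:
        k = self.keys.index(key)
        return float(self.sigma[term][k, k])


@dataclasses.dataclass
class MMESystem:
    coeff: np.ndarray
    rhs: np.ndarray
    layout: dict  # (effect, key, level) -> index; fixed as ("fixed", key, "")


@dataclasses.dataclass
class BreedingValueSet:
    data: pd.DataFrame  # columns: id, trait, site, bv, pev
    label: str
    varcomp: VarianceComponents | None = None

    def site_averaged(self, trait: str) -> pd.Series:
        d = self.data[self.data["trait"] == trait]
        return d.groupby("id")["bv"].mean()

    def per_site(self, trait: str) -> pd.DataFrame:
        return self.data[self.data["trait"] == trait].pivot(
            index="id", columns="site", values="bv"
        )


# ---------------------------------------------------------------------------
# internal problem container


class _Problem:
    """Record-level arrays shared by the REML engine and the MME builder."""

    def __init__(self, spec: ModelSpec, phen: PhenotypeTable):
        keys = spec.keys
        kidx = {k: j for j, k in enumerate(keys)}
        df = phen.data
        df = df[df["trait"].isin(spec.traits) & df["site"].isin(spec.sites)]
        if df.empty:
            raise ValidationError("no phenotype records match the model spec")
        df = df.assign(_key=[kidx[(t, s)] for t, s in zip(df["trait"], df["site"])])
        df = df.sort_values(["id", "_key"], kind="stable").reset_index(drop=True)

        self.spec = spec
        self.keys = keys
        self.q = len(keys)
        self.y = df["value"].to_numpy(dtype=float)
        self.N = len(self.y)
        self.rec_key = df["_key"].to_numpy()
        self.rec_id = df["id"].to_numpy()
        self.individuals = list(dict.fromkeys(self.rec_id))  # sorted-by-appearance
        ind_idx = {i: k for k, i in enumerate(self.individuals)}
        self.rec_ind = np.array([ind_idx[i] for i in self.rec_id])
        self.site_of = dict(df.drop_duplicates("id")[["id", "site"]].itertuples(index=False))

        # term level structures: genetic terms indexed by individual
        self.terms = []
        for name, K in spec.random_terms:
            pos = {i: k for k, i in enumerate(K.ids)}
            missing = [i for i in self.individuals if i not in pos]
            if missing:
                raise ValidationError(
                    f"term {name!r}: relationship matrix lacks individuals {missing[:5]}"
                )
            sub = [pos[i] for i in self.individuals]
            Kobs = K.values[np.ix_(sub, sub)]
            self.terms.append({"name": name, "K": Kobs, "full": K})
        self.rec_lev = self.rec_ind  # all genetic terms use individual levels

        # residual bookkeeping: per-individual record blocks, grouped by
        # (site, trait pattern) for batched algebra
        self.rec_trait = df["trait"].to_numpy()
        self.trait_of_key = [t for t, _ in keys]
        self.site_of_key = [s for _, s in keys]
        starts = np.flatnonzero(np.r_[1, np.diff(self.rec_ind)])
        bounds = np.r_[starts, self.N]
        self.groups = {}
        for g in range(len(starts)):
            lo, hi = bounds[g], bounds[g + 1]
            traits = tuple(self.trait_of_key[k] for k in self.rec_key[lo:hi])
            site = self.site_of_key[self.rec_key[lo]]
            self.groups.setdefault((site, traits), []).append(np.arange(lo, hi))
        self.sites = sorted({s for _, s in keys})
        self.traits_at_site = {
            s: [t for t in spec.traits] for s in self.sites
        }

        # gathered relationship matrices (fixed across iterations)
        self.Kg = [t["K"][np.ix_(self.rec_lev, self.rec_lev)] for t in self.terms]
        self.same_ind = self.rec_ind[:, None] == self.rec_ind[None, :]
        self.Ikey = np.zeros((self.N, self.q))
        self.Ikey[np.arange(self.N), self.rec_key] = 1.0
        self.X = self.Ikey.copy()  # intercept per response key

    # ------ covariance assembly ------

    def key_residual(self, residual: dict) -> np.ndarray:
        q = self.q
        R = np.zeros((q, q))
        for a in range(q):
            for b in range(q):
                sa, sb = self.site_of_key[a], self.site_of_key[b]
                if sa != sb:
                    continue
                traits, mat = residual[sa]
                ta, tb = self.trait_of_key[a], self.trait_of_key[b]
                R[a, b] = mat[traits.index(ta), traits.index(tb)]
        return R

    def build_V(self, sigma: dict, residual: dict):
        kk = self.rec_key
        V = np.zeros((self.N, self.N))
        for t, Kg in zip(self.terms, self.Kg):
            V += sigma[t["name"]][np.ix_(kk, kk)] * Kg
        Rkey = self.key_residual(residual)
        Rfull = np.where(self.same_ind, Rkey[np.ix_(kk, kk)], 0.0)
        V += Rfull
        return V, Rfull


def _psd_clip(M: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    """Eigen-clip to keep covariance matrices positive definite."""
    M = 0.5 * (M + M.T)
    w, U = np.linalg.eigh(M)
    floor = max(w.max(), 0.0) * floor_frac
    floor = floor if floor > 0 else 1e-12
    w = np.clip(w, floor, None)
    return (U * w) @ U.T


def _projection(prob: _Problem, V: np.ndarray):
    """Return (P, Py, restricted log-likelihood)."""
    try:
        c, low = sla.cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise ValidationError(f"covariance matrix not positive definite: {e}") from e
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = sla.cho_solve((c, low), np.eye(prob.N), check_finite=False)
    VinvX = Vinv @ prob.X
    XtVinvX = prob.X.T @ VinvX
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise ValidationError("X'V^-1X not positive definite")
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    Py = P @ prob.y
    ll = -0.5 * (logdetV + logdetX + float(prob.y @ Py))
    if not np.isfinite(ll):
        raise ValidationError("non-finite restricted log-likelihood")
    return P, Py, ll


def _em_step(prob: _Problem, sigma: dict, residual: dict, P, Py):
    """One EM-REML update of all (co)variance matrices."""
    new_sigma = {}
    for t, Kg in zip(prob.terms, prob.Kg):
        S = sigma[t["name"]]
        K = t["K"]
        n_t = K.shape[0]
        U0 = np.zeros((n_t, prob.q))
        np.add.at(U0, (prob.rec_lev, prob.rec_key), Py)
        M1 = U0.T @ (K @ U0)  # v_r' K v_s
        T = prob.Ikey.T @ (P * Kg) @ prob.Ikey  # tr(Z_r' P Z_s K)
        S_new = (S @ M1 @ S + n_t * S - S @ T @ S) / n_t
        new_sigma[t["name"]] = _psd_clip(S_new)

    # residual: exact EM with complete per-site trait records; pairwise
    # divisors keep the update defined when some trait records are absent
    Rkey = prob.key_residual(residual)
    kk = prob.rec_key
    Rfull = np.where(prob.same_ind, Rkey[np.ix_(kk, kk)], 0.0)
    ehat = Rfull @ Py
    sums = {s: np.zeros_like(residual[s][1]) for s in prob.sites}
    counts = {s: np.zeros_like(residual[s][1]) for s in prob.sites}
    for (site, traits), blocks in prob.groups.items():
        recs = np.stack(blocks)  # (n_i, b)
        b = recs.shape[1]
        t_idx = [residual[site][0].index(t) for t in traits]
        Rb = residual[site][1][np.ix_(t_idx, t_idx)]
        Pb = P[recs[:, :, None], recs[:, None, :]]  # (n_i, b, b)
        Qb = np.einsum("ij,njk,kl->nil", Rb, Pb, Rb)
        Eb = ehat[recs]  # (n_i, b)
        contrib = Eb[:, :, None] * Eb[:, None, :] + Rb[None, :, :] - Qb
        csum = contrib.sum(axis=0)
        for a in range(b):
            for c2 in range(b):
                sums[site][t_idx[a], t_idx[c2]] += csum[a, c2]
                counts[site][t_idx[a], t_idx[c2]] += recs.shape[0]
    new_residual = {}
    for s in prob.sites:
        traits, old = residual[s]
        mat = old.copy()
        obs = counts[s] > 0
        mat[obs] = sums[s][obs] / counts[s][obs]
        new_residual[s] = (traits, _psd_clip(mat))
    return new_sigma, new_residual


def _default_init(prob: _Problem, spec: ModelSpec) -> VarianceComponents:
    """Half the phenotypic variance to the genetic terms (split equally),
    half to the residual; 0.1·sqrt(v_i v_j) genetic covariance between
    sites for the same trait to break symmetry."""
    q = prob.q
    vp = np.empty(q)
    for k in range(q):
        vals = prob.y[prob.rec_key == k]
        vp[k] = vals.var() if len(vals) > 1 else 1.0
    vp = np.where(vp > 0, vp, 1.0)
    n_terms = len(spec.random_terms)
    sigma = {}
    for name, _ in spec.random_terms:
        S = np.zeros((q, q))
        diag = 0.5 * vp / n_terms
        np.fill_diagonal(S, diag)
        for a in range(q):
            for b in range(q):
                if a != b and prob.trait_of_key[a] == prob.trait_of_key[b]:
                    S[a, b] = 0.1 * np.sqrt(diag[a] * diag[b])
        sigma[name] = _psd_clip(S)
    residual = {}
    for s in prob.sites:
        traits = prob.traits_at_site[s]
        mat = np.zeros((len(traits), len(traits)))
        for it, t in enumerate(traits):
            if (t, s) in prob.keys:
                mat[it, it] = 0.5 * vp[prob.keys.index((t, s))]
            else:
                mat[it, it] = 0.5
        residual[s] = (traits, mat)
    return VarianceComponents(list(prob.keys), sigma, residual)


def _param_list(prob: _Problem):
    """Ordered parameter labels: term upper triangles, then residual blocks."""
    labels = []
    for t in prob.terms:
        for j in range(prob.q):
            for l in range(j, prob.q):
                labels.append(("sigma", t["name"], j, l))
    for s in prob.sites:
        traits = prob.traits_at_site[s]
        for a in range(len(traits)):
            for b in range(a, len(traits)):
                labels.append(("residual", s, traits[a], traits[b]))
    return labels


def _ai_matrix(prob: _Problem, sigma, residual, P, Py):
    """Average-information matrix over all (co)variance parameters."""
    labels = _param_list(prob)
    kk = prob.rec_key
    tvecs = np.empty((prob.N, len(labels)))
    for i, lab in enumerate(labels):
        if lab[0] == "sigma":
            _, name, j, l = lab
            ti = [t["name"] for t in prob.terms].index(name)
            mask = (kk[:, None] == j) & (kk[None, :] == l)
            if j != l:
                mask = mask | ((kk[:, None] == l) & (kk[None, :] == j))
            dV = np.where(mask, prob.Kg[ti], 0.0)
        else:
            _, s, ta, tb = lab
            ka = prob.keys.index((ta, s)) if (ta, s) in prob.keys else None
            kb = prob.keys.index((tb, s)) if (tb, s) in prob.keys else None
            if ka is None or kb is None:
                tvecs[:, i] = 0.0
                continue
            mask = (kk[:, None] == ka) & (kk[None, :] == kb)
            if ka != kb:
                mask = mask | ((kk[:, None] == kb) & (kk[None, :] == ka))
            dV = np.where(mask & prob.same_ind, 1.0, 0.0)
        tvecs[:, i] = dV @ Py
    PT = P @ tvecs
    AI = 0.5 * tvecs.T @ PT
    return labels, AI


def _pack(prob: _Problem, sigma: dict, residual: dict) -> np.ndarray:
    parts = [sigma[t["name"]].ravel() for t in prob.terms]
    parts += [residual[s][1].ravel() for s in prob.sites]
    return np.concatenate(parts)


def _unpack(prob: _Problem, theta: np.ndarray):
    sigma, residual = {}, {}
    off = 0
    q = prob.q
    for t in prob.terms:
        sigma[t["name"]] = _psd_clip(theta[off : off + q * q].reshape(q, q))
        off += q * q
    for s in prob.sites:
        traits = prob.traits_at_site[s]
        m = len(traits)
        residual[s] = (traits, _psd_clip(theta[off : off + m * m].reshape(m, m)))
        off += m * m
    return sigma, residual


def fit_reml(
    spec: ModelSpec,
    adjusted: PhenotypeTable,
    init: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    accelerate: bool = True,
) -> VarianceComponents:
    """EM-REML to convergence, then one AI round for standard errors.

    Convergence is declared when the relative change of the restricted
    log-likelihood between accepted states falls below ``tol``.  With
    ``accelerate`` (default) the EM fixed-point iteration is extrapolated
    by safeguarded SQUAREM steps: two EM updates per cycle plus a vector
    extrapolation that is only accepted when it does not decrease the
    restricted likelihood, so the recorded trace stays non-decreasing and
    the fixed point is the same as plain EM's.
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    prob = _Problem(spec, adjusted)
    vc = init if init is not None else _default_init(prob, spec)
    th = _pack(prob, vc.sigma, {s: (list(t), m) for s, (t, m) in vc.residual.items()})

    def em(theta):
        """logL at theta and one EM update; returns (ll, theta_new, P, Py)."""
        sigma, residual = _unpack(prob, theta)
        V, _ = prob.build_V(sigma, residual)
        P, Py, ll = _projection(prob, V)
        s_new, r_new = _em_step(prob, sigma, residual, P, Py)
        return ll, _pack(prob, s_new, r_new), P, Py

    def loglik(theta):
        sigma, residual = _unpack(prob, theta)
        V, _ = prob.build_V(sigma, residual)
        _, _, ll = _projection(prob, V)
        return ll

    trace = []
    converged = False
    it = 0
    while it < max_iter:
        ll0, th1, P, Py = em(th)
        it += 1
        if trace and ll0 < trace[-1] - 1e-8 * (abs(trace[-1]) + 1.0):
            log.warning("restricted log-likelihood decreased: %.6f -> %.6f", trace[-1], ll0)
        if trace and abs(ll0 - trace[-1]) < tol * (abs(trace[-1]) + 1.0):
            trace.append(ll0)
            th = th1
            converged = True
            break
        trace.append(ll0)
        if not accelerate or it >= max_iter:
            th = th1
            continue
        ll1, th2, _, _ = em(th1)
        it += 1
        r = th1 - th
        v = th2 - th1 - r
        nv = np.linalg.norm(v)
        if nv > 0:
            alpha = -np.linalg.norm(r) / nv
            th_acc = th - 2.0 * alpha * r + alpha * alpha * v
            try:
                ll_acc = loglik(th_acc)
            except ValidationError:
                ll_acc = -np.inf
            th = th_acc if ll_acc >= ll1 else th2
        else:
            th = th2

    sigma, residual = _unpack(prob, th)
    V, _ = prob.build_V(sigma, residual)
    P, Py, ll_final = _projection(prob, V)
    trace.append(ll_final)
    labels, AI = _ai_matrix(prob, sigma, residual, P, Py)
    try:
        cov = np.linalg.pinv(AI)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((len(labels), len(labels)), np.nan)
    se = {}
    diag = np.diag(cov)
    for lab, v in zip(labels, diag):
        se[lab] = float(np.sqrt(v)) if v >= 0 else float("nan")

    out = VarianceComponents(
        keys=list(prob.keys),
        sigma=sigma,
        residual=residual,
        param_labels=labels,
        cov_params=cov,
        se=se,
        loglik_trace=trace,
        converged=converged,
        n_iterations=it,
    )
    if not converged:
        log.warning("EM-REML hit max_iter=%d without meeting tol=%g", max_iter, tol)
    return out


# ---------------------------------------------------------------------------
# Henderson mixed-model equations


def _safe_inverse(K: RelationshipMatrix) -> np.ndarray:
    try:
        c, low = sla.cho_factor(K.values + 0.0, lower=True)
    except np.linalg.LinAlgError:
        raise ValidationError(
            f"{K.kind}-matrix is singular and cannot enter the MME; blend it "
            "toward the identity first (relmat.blend)"
        )
    return sla.cho_solve((c, low), np.eye(K.n))


def assemble_mme(
    spec: ModelSpec, adjusted: PhenotypeTable, varcomp: VarianceComponents
) -> MMESystem:
    """Henderson MME with random blocks (Σ⁻¹ across keys) ⊗ (K⁻¹ across levels).

    Random terms cover every individual in their relationship matrix, so
    ungenotyped/unphenotyped parents in A obtain predictions too.
    """
    prob = _Problem(spec, adjusted)
    q = prob.q
    Rkey = prob.key_residual(varcomp.residual)

    # design: fixed (q columns) then term blocks ordered (key, level)
    sizes = [t["full"].n for t in prob.terms]
    dim = q + sum(q * n for n in sizes)
    layout = {}
    for j, key in enumerate(prob.keys):
        layout[("fixed", key, "")] = j
    off = q
    term_offsets = []
    for t, n in zip(prob.terms, sizes):
        term_offsets.append(off)
        for j, key in enumerate(prob.keys):
            for i, ind in enumerate(t["full"].ids):
                layout[(t["name"], key, ind)] = off + j * n + i
        off += q * n

    W = np.zeros((prob.N, dim))
    W[np.arange(prob.N), prob.rec_key] = 1.0
    for t, n, o in zip(prob.terms, sizes, term_offsets):
        pos = {i: k for k, i in enumerate(t["full"].ids)}
        lev = np.array([pos[i] for i in prob.individuals])[prob.rec_lev]
        W[np.arange(prob.N), o + prob.rec_key * n + lev] = 1.0

    # R^-1 applied per individual block
    RinvW = np.empty_like(W)
    for (site, traits), blocks in prob.groups.items():
        recs = np.stack(blocks)
        t_idx = [varcomp.residual[site][0].index(t) for t in traits]
        Rb = varcomp.residual[site][1][np.ix_(t_idx, t_idx)]
        Rbinv = np.linalg.inv(Rb)
        RinvW[recs.ravel()] = np.einsum(
            "ab,nbd->nad", Rbinv, W[recs]
        ).reshape(-1, dim)

    C = W.T @ RinvW
    rhs = RinvW.T @ prob.y
    for t, n, o in zip(prob.terms, sizes, term_offsets):
        Sinv = np.linalg.inv(_psd_clip(varcomp.sigma[t["name"]]))
        Kinv = _safe_inverse(t["full"])
        C[o : o + q * n, o : o + q * n] += np.kron(Sinv, Kinv)
    return MMESystem(C, rhs, layout)


def predict_blup(
    spec: ModelSpec, adjusted: PhenotypeTable, varcomp: VarianceComponents
) -> BreedingValueSet:
    """Solve the MME; breeding values per (individual, trait, site) with PEV.

    PEV_i is the corresponding diagonal entry of the inverse coefficient
    matrix; where blending pushes PEV above the genetic variance it is
    clamped to it (theoretical accuracy 0 rather than imaginary).
    """
    mme = assemble_mme(spec, adjusted, varcomp)
    try:
        c, low = sla.cho_factor(mme.coeff, lower=True)
    except np.linalg.LinAlgError as e:
        raise ValidationError(f"MME coefficient matrix not positive definite: {e}") from e
    Cinv = sla.cho_solve((c, low), np.eye(mme.coeff.shape[0]))
    sol = Cinv @ mme.rhs

    add_name = spec.random_terms[0][0]
    K = spec.random_terms[0][1]
    rows = []
    n_clamped = 0
    for key in spec.keys:
        var_g = varcomp.genetic_variance(add_name, key)
        for ind in K.ids:
            idx = mme.layout[(add_name, key, ind)]
            pev = float(Cinv[idx, idx])
            if pev > var_g:
                pev = var_g
                n_clamped += 1
            rows.append((ind, key[0], key[1], float(sol[idx]), pev))
    if n_clamped:
        log.warning("PEV clamped to the genetic variance for %d entries", n_clamped)
    df = pd.DataFrame(rows, columns=["id", "trait", "site", "bv", "pev"])
    return BreedingValueSet(df, spec.label, varcomp)


# ---------------------------------------------------------------------------
# stage 1: adjust raw phenotypes for the within-site design (replications)


def adjust_stage1(
    phenotypes: PhenotypeTable,
    pedigree: PedigreeTable,
    genetic_term: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PhenotypeTable:
    """Subtract predicted replication effects, per site and trait.

    Each (site, trait) is fitted separately with intercept + random
    replication + (optionally) a pedigree-based additive term + residual;
    the genetic term keeps replication predictions from soaking up family
    structure.  Site means are retained.  A site with a single replication
    is returned unchanged with a warning.
    """
    A = build_A(pedigree) if genetic_term else None
    df = phenotypes.data.copy()
    df["_adj"] = df["value"].astype(float)
    for (site, trait), sub in df.groupby(["site", "trait"], sort=True):
        reps = sorted(sub["rep"].unique())
        if len(reps) < 2:
            warnings.warn(
                f"site {site!r}, trait {trait!r}: single replication, "
                "stage-1 adjustment is the identity"
            )
            continue
        rep_hat = _fit_rep_effects(sub, A, trait, site, tol, max_iter)
        df.loc[sub.index, "_adj"] = sub["value"].to_numpy() - np.array(
            [rep_hat[r] for r in sub["rep"]]
        )
    out = df.drop(columns=["value"]).rename(columns={"_adj": "value"})
    return PhenotypeTable(out[["id", "site", "rep", "trait", "value"]], phenotypes.traits)


def _fit_rep_effects(sub: pd.DataFrame, A, trait, site, tol, max_iter) -> dict:
    """REML-fitted BLUP of replication effects for one (site, trait)."""
    y = sub["value"].to_numpy(dtype=float)
    n = len(y)
    reps = sorted(sub["rep"].unique())
    rep_idx = np.array([reps.index(r) for r in sub["rep"]])
    Zr = np.zeros((n, len(reps)))
    Zr[np.arange(n), rep_idx] = 1.0
    X = np.ones((n, 1))

    covs = [Zr @ Zr.T]
    qs = [len(reps)]
    if A is not None:
        pos = {i: k for k, i in enumerate(A.ids)}
        idx = [pos[i] for i in sub["id"]]
        covs.append(A.values[np.ix_(idx, idx)])
        qs.append(n)

    vp = y.var() if n > 1 else 1.0
    theta = np.full(len(covs) + 1, vp / (len(covs) + 1))  # [rep, (add,) resid]
    last_ll = -np.inf
    for _ in range(max_iter):
        V = sum(t * C for t, C in zip(theta, covs)) + theta[-1] * np.eye(n)
        c, low = sla.cho_factor(V, lower=True)
        Vinv = sla.cho_solve((c, low), np.eye(n))
        VinvX = Vinv @ X
        XtVX = X.T @ VinvX
        P = Vinv - VinvX @ np.linalg.solve(XtVX, VinvX.T)
        Py = P @ y
        ll = -0.5 * (
            2 * np.sum(np.log(np.diag(c)))
            + np.linalg.slogdet(XtVX)[1]
            + float(y @ Py)
        )
        new = theta.copy()
        for k, (C, qk) in enumerate(zip(covs, qs)):
            new[k] = theta[k] + theta[k] ** 2 * (Py @ C @ Py - np.sum(P * C)) / qk
        new[-1] = theta[-1] + theta[-1] ** 2 * (Py @ Py - np.trace(P)) / n
        new = np.clip(new, 1e-10 * vp, None)
        if abs(ll - last_ll) < tol * (abs(ll) + 1.0):
            theta = new
            break
        theta, last_ll = new, ll

    V = sum(t * C for t, C in zip(theta, covs)) + theta[-1] * np.eye(n)
    Vinv = np.linalg.inv(V)
    VinvX = Vinv @ X
    P = Vinv - VinvX @ np.linalg.solve(X.T @ VinvX, VinvX.T)
    u_rep = theta[0] * (Zr.T @ (P @ y))
    return dict(zip(reps, u_rep))


# ---------------------------------------------------------------------------
# convenience wrapper


def fit_model(
    adjusted: PhenotypeTable,
    traits: list[str] | str,
    relationships: dict[str, RelationshipMatrix],
    label: str | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[VarianceComponents, BreedingValueSet]:
    """Fit a multi-site model for one trait (model family [single-trait]) or
    several traits jointly, and return variance components plus BLUPs.

    ``relationships`` maps term names ('additive', optionally 'dominance'
    and 'epistatic') to relationship matrices.
    """
    if isinstance(traits, str):
        traits = [traits]
    sites = adjusted.sites
    terms = [(name, K) for name, K in relationships.items()]
    spec = ModelSpec(list(traits), sites, terms, label or "GBLUP-A")
    vc = fit_reml(spec, adjusted, tol=tol, max_iter=max_iter)
    bvs = predict_blup(spec, adjusted, vc)
    return vc, bvs
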