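"""Heritability, theoretical accuracy, expected gain, and optimum contribution selection.

Narrow-sense heritability is computed per trait from site-averaged variance
components, h² = σ̄²_a / (σ̄²_a + σ̄²_e); for additive+dominance+epistatic
models the denominator also carries the dominance and epistatic variances.
Theoretical accuracy per individual is TA_i = sqrt(1 − PEV_i/σ̂²_a).
Optimum contribution selection (OCS) maximises genetic gain over candidate
subsets with equal contributions, under a group co-ancestry ceiling ΔF and
optional auxiliary trait constraints (e.g. no wood-density loss), via exact
branch-and-bound enumeration for small candidate lists and a greedy+swap
heuristic with seeded restarts otherwise.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd

from .io import ValidationError
from .mixed_models import BreedingValueSet, VarianceComponents
from .relmat import RelationshipMatrix

__all__ = [
    "heritability",
    "theoretical_accuracy",
    "expected_gain",
    "group_coancestry",
    "OCSConfig",
    "OCSolution",
    "InfeasibleOCSError",
    "ocs_optimize",
]

log = logging.getLogger(__name__)

_GENETIC_TERMS = ("additive", "dominance", "epistatic")


def _labels(vc: VarianceComponents) -> list:
    """Parameter labels in the AI-matrix order (synthesised when the
    components were supplied by hand rather than fitted)."""
    if vc.param_labels is not None:
        return vc.param_labels
    labels = []
    q = len(vc.keys)
    for term in vc.sigma:
        for j in range(q):
            for l in range(j, q):
                labels.append(("sigma", term, j, l))
    for s in sorted(vc.residual):
        traits, _ = vc.residual[s]
        for a in range(len(traits)):
            for b in range(a, len(traits)):
                labels.append(("residual", s, traits[a], traits[b]))
    return labels


def _theta_to_h2(vc: VarianceComponents, trait: str, theta: np.ndarray) -> float:
    """h² for one trait as a function of the flat parameter vector."""
    lab = _labels(vc)
    num = 0.0
    den_g = 0.0
    den_e = []
    n_sites_g = 0
    sites = sorted({s for _, s in vc.keys})
    for s in sites:
        key = (trait, s)
        if key not in vc.keys:
            continue
        j = vc.keys.index(key)
        for term in vc.sigma:
            i = lab.index(("sigma", term, j, j))
            if term == "additive":
                num += theta[i]
            den_g += theta[i]
        i = lab.index(("residual", s, trait, trait))
        den_e.append(theta[i])
        n_sites_g += 1
    num /= n_sites_g
    den = den_g / n_sites_g + float(np.mean(den_e))
    return num / den


def _theta_vector(vc: VarianceComponents) -> np.ndarray:
    labels = _labels(vc)
    theta = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab[0] == "sigma":
            _, term, j, l = lab
            theta[i] = vc.sigma[term][j, l]
        else:
            _, s, ta, tb = lab
            traits, mat = vc.residual[s]
            theta[i] = mat[traits.index(ta), traits.index(tb)]
    return theta


def heritability(varcomp: VarianceComponents, model: str = "") -> dict:
    """Per-trait h² with a delta-method standard error from the AI matrix.

    Genetic and residual variances are averaged across sites before the
    ratio is taken.  All genetic terms present (additive, dominance,
    epistatic) enter the denominator; only the additive variance enters
    the numerator.
    """
    traits = list(dict.fromkeys(t for t, _ in varcomp.keys))
    theta = _theta_vector(varcomp)
    for term, S in varcomp.sigma.items():
        if np.any(np.diag(S) < 0):
            raise ValidationError(f"negative {term} variance estimate")
    out = {}
    for trait in traits:
        h2 = _theta_to_h2(varcomp, trait, theta)
        se = float("nan")
        if varcomp.cov_params is not None:
            grad = np.zeros_like(theta)
            for i in range(len(theta)):
                step = 1e-6 * max(abs(theta[i]), 1e-3)
                tp, tm = theta.copy(), theta.copy()
                tp[i] += step
                tm[i] -= step
                grad[i] = (
                    _theta_to_h2(varcomp, trait, tp)
                    - _theta_to_h2(varcomp, trait, tm)
                ) / (2 * step)
            var = float(grad @ varcomp.cov_params @ grad)
            se = float(np.sqrt(var)) if var >= 0 else float("nan")
        out[trait] = (float(h2), se)
    return out


def theoretical_accuracy(
    bvs: BreedingValueSet, varcomp: VarianceComponents
) -> pd.DataFrame:
    """TA_i = sqrt(1 − PEV_i / σ̂²_a) per (individual, trait, site).

    PEV above the additive variance is clamped (accuracy 0, with a log
    message) — this can happen under relationship-matrix blending.
    """
    rows = []
    n_clamped = 0
    for (trait, site), d in bvs.data.groupby(["trait", "site"], sort=False):
        var_a = varcomp.genetic_variance("additive", (trait, site))
        if var_a <= 0:
            raise ValidationError(
                f"additive variance is zero for {(trait, site)}: TA undefined"
            )
        ratio = 1.0 - d["pev"].to_numpy() / var_a
        n_clamped += int((ratio < 0).sum())
        ta = np.sqrt(np.clip(ratio, 0.0, None))
        rows.append(d.assign(ta=ta)[["id", "trait", "site", "ta"]])
    if n_clamped:
        log.warning("theoretical accuracy clamped to 0 for %d entries", n_clamped)
    return pd.concat(rows, ignore_index=True)


def expected_gain(
    bvs: BreedingValueSet, trait: str, n_top: int, trait_mean: float
) -> float:
    """Expected gain (% of the trait mean) of truncation-selecting the
    ``n_top`` individuals with the highest site-averaged breeding value."""
    if trait_mean == 0:
        raise ValidationError("trait mean must be non-zero")
    sa = bvs.site_averaged(trait)
    if sa.empty:
        raise ValidationError(f"trait {trait!r} absent from breeding values")
    if n_top > len(sa):
        raise ValidationError("n_top exceeds the number of candidates")
    top = sa.sort_values(ascending=False).iloc[:n_top]
    return float(100.0 * top.mean() / trait_mean)


def group_coancestry(c: np.ndarray, K: RelationshipMatrix) -> tuple[float, float]:
    """(c'Kc/2, mean pairwise relationship among contributing individuals).

    The first is the classical group co-ancestry of the contribution
    vector; the second (off-diagonal mean of K restricted to positive
    contributions; 0 for a single individual) is the reporting alternative.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (K.n,):
        raise ValidationError("contribution vector does not match K")
    if np.any(c < -1e-12) or abs(c.sum() - 1.0) > 1e-8:
        raise ValidationError("contributions must be non-negative and sum to 1")
    gc = float(c @ K.values @ c) / 2.0
    sel = np.flatnonzero(c > 0)
    if len(sel) < 2:
        mp = 0.0
    else:
        sub = K.values[np.ix_(sel, sel)]
        mp = float((sub.sum() - np.trace(sub)) / (len(sel) * (len(sel) - 1)))
    return gc, mp


# ---------------------------------------------------------------------------
# optimum contribution selection


@dataclasses.dataclass
class OCSConfig:
    n_max: int = 30
    delta_f_limit: float | None = None
    coancestry_definition: str = "mean_pairwise"  # or "group"
    auxiliary_constraints: list = dataclasses.field(default_factory=list)
    # each: (trait, ">=" or "<=", bound on the selected set's mean BV)
    exact_max_candidates: int = 25
    n_restarts: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_max < 1:
            raise ValidationError("n_max must be >= 1")
        if self.delta_f_limit is not None and self.delta_f_limit < 0:
            raise ValidationError("delta_f_limit must be >= 0")
        if self.coancestry_definition not in ("mean_pairwise", "group"):
            raise ValidationError("coancestry_definition must be mean_pairwise|group")


@dataclasses.dataclass
class OCSolution:
    selected: list[str]
    contributions: np.ndarray
    gain: dict  # trait -> mean BV of selected (objective scale: standardized)
    gain_raw: dict  # trait -> mean raw BV of selected
    delta_f: float
    solver: str  # exact | heuristic
    optimal: bool
    objective: float


class InfeasibleOCSError(ValidationError):
    """No candidate subset satisfies the constraints."""


class _OCSProblem:
    def __init__(self, ids, score, K, bv_by_trait, config):
        self.ids = ids
        self.score = score  # composite objective per candidate
        self.K = K
        self.bv = bv_by_trait  # trait -> raw site-averaged BV array
        self.cfg = config

    def delta_f(self, sel: list[int]) -> float:
        if len(sel) == 1:
            sub = self.K[np.ix_(sel, sel)]
            return float(sub[0, 0]) / 2.0 if self.cfg.coancestry_definition == "group" else 0.0
        sub = self.K[np.ix_(sel, sel)]
        if self.cfg.coancestry_definition == "group":
            m = len(sel)
            return float(sub.sum()) / (2.0 * m * m)
        return float((sub.sum() - np.trace(sub)) / (len(sel) * (len(sel) - 1)))

    def feasible(self, sel: list[int]) -> bool:
        if not sel or len(sel) > self.cfg.n_max:
            return False
        if self.cfg.delta_f_limit is not None:
            if self.delta_f(sel) > self.cfg.delta_f_limit + 1e-12:
                return False
        for trait, op, bound in self.cfg.auxiliary_constraints:
            mean = float(np.mean(self.bv[trait][sel]))
            if op == ">=" and mean < bound - 1e-12:
                return False
            if op == "<=" and mean > bound + 1e-12:
                return False
        return True

    def objective(self, sel: list[int]) -> float:
        # per-slot gain: unfilled slots of the n_max deployment contribute 0,
        # so the unconstrained optimum is exactly truncation selection and
        # relaxing constraints can never decrease the optimum
        return float(np.sum(self.score[sel])) / self.cfg.n_max


def _exact_solve(p: _OCSProblem):
    """Branch-and-bound over subsets in descending-score order.

    The bound at a node adds every remaining positive score that still fits;
    constraints are only checked when a node is recorded, because adding an
    unrelated candidate can repair a ΔF or auxiliary-trait violation.
    """
    order = np.argsort(-p.score, kind="stable")
    s = p.score[order]
    n = len(s)
    pos_prefix = np.concatenate([[0.0], np.cumsum(np.clip(s, 0.0, None))])
    best = {"obj": -np.inf, "sel": None}

    def dfs(i, sel, cur_sum):
        if sel:
            obj = cur_sum / p.cfg.n_max
            if obj > best["obj"] + 1e-12 and p.feasible([int(order[k]) for k in sel]):
                best["obj"] = obj
                best["sel"] = [int(order[k]) for k in sel]
        if i >= n or len(sel) >= p.cfg.n_max:
            return
        room = min(p.cfg.n_max - len(sel), n - i)
        ub = (cur_sum + pos_prefix[i + room] - pos_prefix[i]) / p.cfg.n_max
        if ub <= best["obj"] + 1e-12:
            return
        dfs(i + 1, sel + [i], cur_sum + s[i])
        dfs(i + 1, sel, cur_sum)

    dfs(0, [], 0.0)
    return best["sel"], best["obj"]


def _heuristic_solve(p: _OCSProblem):
    rng = np.random.default_rng(p.cfg.seed)
    n = len(p.score)
    best_sel, best_obj = None, -np.inf

    def try_improve(sel: list[int]):
        nonlocal best_sel, best_obj
        if p.feasible(sel):
            obj = p.objective(sel)
            if obj > best_obj + 1e-12:
                best_sel, best_obj = list(sel), obj

    order = np.argsort(-p.score, kind="stable")
    for restart in range(p.cfg.n_restarts):
        for size in range(1, p.cfg.n_max + 1):
            if restart == 0:
                sel = list(order[:size])  # greedy truncation start
            else:
                sel = list(rng.choice(n, size=min(size, n), replace=False))
            try_improve(sel)
            # pairwise swap local search on the feasible incumbent
            improved = True
            guard = 0
            while improved and guard < 200:
                improved = False
                guard += 1
                cur = set(sel)
                outside = [j for j in order if j not in cur]
                for a in list(sel):
                    for b in outside[:50]:
                        cand = [b if x == a else x for x in sel]
                        if p.feasible(cand) and p.objective(cand) > p.objective(sel) + 1e-12:
                            sel = cand
                            improved = True
                            break
                    if improved:
                        break
            try_improve(sel)
    return best_sel, best_obj


def ocs_optimize(
    bvs: BreedingValueSet,
    K: RelationshipMatrix,
    config: OCSConfig,
    objective_traits: list[str],
) -> OCSolution:
    """Select up to ``n_max`` equally-contributing individuals maximising the
    standardized, equally-weighted mean breeding value of the objective
    traits, under the ΔF ceiling and auxiliary trait constraints.

    The optimiser may return fewer than ``n_max`` individuals when that
    raises the constrained optimum.
    """
    ids = [i for i in K.ids if i in set(bvs.data["id"])]
    if not ids:
        raise ValidationError("no candidates shared between K and the breeding values")
    pos = {i: k for k, i in enumerate(K.ids)}
    idx = [pos[i] for i in ids]
    Kc = K.values[np.ix_(idx, idx)]

    bv_by_trait = {}
    score = np.zeros(len(ids))
    traits = list(dict.fromkeys(bvs.data["trait"]))
    for trait in traits:
        sa = bvs.site_averaged(trait).reindex(ids)
        if sa.isna().any():
            raise ValidationError(f"missing breeding values for trait {trait!r}")
        bv_by_trait[trait] = sa.to_numpy()
    for trait in objective_traits:
        if trait not in bv_by_trait:
            raise ValidationError(f"objective trait {trait!r} absent")
        v = bv_by_trait[trait]
        sd = v.std()
        score += v / (sd if sd > 0 else 1.0)  # unit variance, no re-centring
    score /= len(objective_traits)

    p = _OCSProblem(ids, score, Kc, bv_by_trait, config)
    if len(ids) <= config.exact_max_candidates:
        sel, obj = _exact_solve(p)
        solver, optimal = "exact", True
    else:
        sel, obj = _heuristic_solve(p)
        solver, optimal = "heuristic", False
    if sel is None:
        raise InfeasibleOCSError(
            f"no subset of <= {config.n_max} candidates satisfies "
            f"delta_f <= {config.delta_f_limit} and {config.auxiliary_constraints}"
        )
    sel_ids = [ids[k] for k in sel]
    c = np.zeros(len(ids))
    c[sel] = 1.0 / len(sel)
    gain = {
        t: float(np.mean((bv_by_trait[t] / (bv_by_trait[t].std() or 1.0))[sel]))
        for t in traits
    }
    gain_raw = {t: float(np.mean(bv_by_trait[t][sel])) for t in traits}
    return OCSolution(
        selected=sel_ids,
        contributions=c,
        gain=gain,
        gain_raw=gain_raw,
        delta_f=p.delta_f(sel),
        solver=solver,
        optimal=optimal,
        objective=obj,
    )
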