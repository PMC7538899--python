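"""REML estimation for the nested linear mixed-effects models of the pipeline.

Two random-effect structures cover the pipeline's models:

* ``nested_intercepts`` — a random intercept per patient and per eye within
  patient (the repeated-measures agreement models);
* ``nested_intercept_slope`` — correlated random intercept and years-slope at
  both the patient and the eye-within-patient level, each with an
  unstructured 2x2 covariance (the longitudinal thickness model,
  ``thickness ~ years + group + years:group`` with random ``~ 1 + years``
  per patient and per eye).

A single-level ``patient_intercept`` structure is also provided for designs
without an eye level (e.g. balanced one-way data).

Estimation maximizes the restricted likelihood over a log-SD / log-Cholesky
parameterization of the relative (to residual variance) random-effect
covariances, with the residual variance and fixed effects profiled out in
closed form. Clusters (patients) sharing a shape are evaluated with batched
linear algebra, which keeps bootstrap refits cheap. Denominator degrees of
freedom follow the containment ("inner-outer") rule: each fixed term is
tested against the grouping level at which it varies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "LMMFit",
    "NestedMixedModel",
    "fit_reml",
    "wald_inference",
    "estimate_group_profiles",
]

FIXED_TERMS = ("intercept", "years", "group", "laterality", "years:group")

RANDOM_STRUCTURES = ("nested_intercepts", "nested_intercept_slope", "patient_intercept")

# Containment level of each fixed term: the innermost grouping level at
# which the covariate varies. 1 = between patients, 2 = between eyes within
# patient, 3 = within eye (observation level). The intercept is tested at
# the observation level, matching nlme's convention.
_TERM_LEVEL = {
    "intercept": 3,
    "years": 3,
    "years:group": 3,
    "group": 1,
    "laterality": 2,
}

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random structure of one mixed model.

    Parameters
    ----------
    response : str
        Name of the response column (a thickness or a difference, µm).
    fixed_terms : tuple of str
        Subset of ``{"intercept", "years", "group", "laterality",
        "years:group"}``. The intercept is mandatory.
    random_structure : str
        One of ``"nested_intercepts"``, ``"nested_intercept_slope"``,
        ``"patient_intercept"``.
    """

    response: str
    fixed_terms: tuple[str, ...] = ("intercept",)
    random_structure: str = "nested_intercepts"

    def __post_init__(self) -> None:
        unknown = [t for t in self.fixed_terms if t not in FIXED_TERMS]
        if unknown:
            raise ValueError(f"unknown fixed terms: {unknown}")
        if "intercept" not in self.fixed_terms:
            raise ValueError("the intercept term is mandatory")
        if "years:group" in self.fixed_terms and not (
            "years" in self.fixed_terms and "group" in self.fixed_terms
        ):
            raise ValueError("years:group requires both years and group main effects")
        if self.random_structure not in RANDOM_STRUCTURES:
            raise ValueError(
                f"random_structure must be one of {RANDOM_STRUCTURES}, "
                f"got {self.random_structure!r}"
            )


# ---------------------------------------------------------------------------
# Cluster preparation and batched REML evaluation
# ---------------------------------------------------------------------------


@dataclass
class _Cluster:
    n: int
    eye_sizes: tuple[int, ...]
    y: np.ndarray          # (n,)
    X: np.ndarray          # (n, p)
    years: np.ndarray      # (n,)
    signature: tuple


@dataclass
class _Group:
    """Clusters of identical shape, stacked for batched evaluation."""

    n: int
    eye_sizes: tuple[int, ...]
    XY: np.ndarray         # (B, n, p+1): fixed design with response appended
    X: np.ndarray          # (B, n, p)
    y: np.ndarray          # (B, n)
    Zp: np.ndarray         # (B, n, qp)
    Ze: np.ndarray | None  # (B, n, E*qe)
    # Shared-W pattern blocks (intercept-only structures): W is identical
    # across the batch because Z contains no covariates.
    Jp: np.ndarray | None = None
    Je: np.ndarray | None = None


class ClusterSet:
    """Per-patient data split into shape-batched groups for REML evaluation."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        years: np.ndarray,
        patient_codes: np.ndarray,
        eye_codes: np.ndarray,
        structure: str,
    ) -> None:
        self.structure = structure
        self.qp = 2 if structure == "nested_intercept_slope" else 1
        self.qe = {"nested_intercepts": 1, "nested_intercept_slope": 2,
                   "patient_intercept": 0}[structure]
        self.shared_w = structure in ("nested_intercepts", "patient_intercept")
        self.p = X.shape[1]

        order = np.lexsort((eye_codes, patient_codes))
        y, X, years = y[order], X[order], years[order]
        patient_codes, eye_codes = patient_codes[order], eye_codes[order]

        self.clusters: list[_Cluster] = []
        starts = np.flatnonzero(np.r_[True, np.diff(patient_codes) != 0])
        bounds = np.r_[starts, len(patient_codes)]
        for s, e in zip(bounds[:-1], bounds[1:]):
            ey = eye_codes[s:e]
            eye_sizes = tuple(np.bincount(pd.factorize(ey)[0]).tolist())
            sig = (e - s, eye_sizes)
            self.clusters.append(
                _Cluster(e - s, eye_sizes, y[s:e], X[s:e], years[s:e], sig)
            )
        self.n_patients = len(self.clusters)
        self.n_eyes = sum(len(c.eye_sizes) for c in self.clusters)
        self.n_obs = len(y)

        self._sig_index: dict[tuple, list[int]] = {}
        for i, c in enumerate(self.clusters):
            self._sig_index.setdefault(c.signature, []).append(i)
        self._stacks: dict[tuple, _Group] = {
            sig: self._stack([self.clusters[i] for i in idx])
            for sig, idx in self._sig_index.items()
        }
        # cluster id -> (signature, slot within that signature's stack)
        self._slot = {}
        for sig, idx in self._sig_index.items():
            for slot, i in enumerate(idx):
                self._slot[i] = (sig, slot)

    # -- construction helpers ------------------------------------------------

    def _zmats(self, c: _Cluster) -> tuple[np.ndarray, np.ndarray | None]:
        if self.qp == 1:
            Zp = np.ones((c.n, 1))
        else:
            Zp = np.column_stack([np.ones(c.n), c.years])
        if self.qe == 0:
            return Zp, None
        E = len(c.eye_sizes)
        Ze = np.zeros((c.n, E * self.qe))
        r = 0
        for e, sz in enumerate(c.eye_sizes):
            Ze[r:r + sz, e * self.qe] = 1.0
            if self.qe == 2:
                Ze[r:r + sz, e * self.qe + 1] = c.years[r:r + sz]
            r += sz
        return Zp, Ze

    def _stack(self, cs: list[_Cluster]) -> _Group:
        n = cs[0].n
        X = np.stack([c.X for c in cs])
        y = np.stack([c.y for c in cs])
        XY = np.concatenate([X, y[:, :, None]], axis=2)
        zs = [self._zmats(c) for c in cs]
        Zp = np.stack([z[0] for z in zs])
        Ze = None if self.qe == 0 else np.stack([z[1] for z in zs])
        g = _Group(n, cs[0].eye_sizes, XY, X, y, Zp, Ze)
        if self.shared_w:
            g.Jp = np.ones((n, n))
            if self.qe:
                blocks = []
                for sz in cs[0].eye_sizes:
                    blocks.append(np.ones((sz, sz)))
                Je = np.zeros((n, n))
                r = 0
                for b in blocks:
                    Je[r:r + b.shape[0], r:r + b.shape[0]] = b
                    r += b.shape[0]
                g.Je = Je
        return g

    # -- group selection -----------------------------------------------------

    def full_groups(self) -> list[_Group]:
        return list(self._stacks.values())

    def resampled_groups(self, cluster_ids: Sequence[int]) -> tuple[list[_Group], int]:
        """Batched groups for a multiset of cluster ids (bootstrap replicate).

        Repeated draws enter as independent clusters. Returns the groups and
        the total observation count.
        """
        by_sig: dict[tuple, list[int]] = {}
        n_obs = 0
        for i in cluster_ids:
            sig, slot = self._slot[i]
            by_sig.setdefault(sig, []).append(slot)
            n_obs += self.clusters[i].n
        groups = []
        for sig, slots in by_sig.items():
            g0 = self._stacks[sig]
            sel = np.asarray(slots)
            g = _Group(
                g0.n, g0.eye_sizes, g0.XY[sel], g0.X[sel], g0.y[sel],
                g0.Zp[sel], None if g0.Ze is None else g0.Ze[sel],
                g0.Jp, g0.Je,
            )
            groups.append(g)
        return groups, n_obs


def _theta_init(structure: str) -> np.ndarray:
    if structure == "nested_intercepts":
        return np.zeros(2)
    if structure == "patient_intercept":
        return np.zeros(1)
    # intercept+slope: relative intercept SD 1, slope SD 0.3, no correlation
    return np.array([0.0, 0.0, np.log(0.3), 0.0, 0.0, np.log(0.3)])


def _theta_bounds(structure: str) -> list[tuple[float, float]]:
    diag = (-10.0, 8.0)
    off = (-60.0, 60.0)
    if structure == "nested_intercepts":
        return [diag, diag]
    if structure == "patient_intercept":
        return [diag]
    return [diag, off, diag, diag, off, diag]


def _theta_to_cov(theta: np.ndarray, structure: str):
    """Relative covariance blocks (Dp, De) from the free parameters."""
    if structure == "nested_intercepts":
        return np.array([[np.exp(2 * theta[0])]]), np.array([[np.exp(2 * theta[1])]])
    if structure == "patient_intercept":
        return np.array([[np.exp(2 * theta[0])]]), None

    def chol(t):
        L = np.array([[np.exp(t[0]), 0.0], [t[1], np.exp(t[2])]])
        return L @ L.T

    return chol(theta[:3]), chol(theta[3:])


class _Profile(NamedTuple):
    crit: float
    beta: np.ndarray
    sigma2: float
    A: np.ndarray  # X' W^-1 X summed over clusters


def _cov_derivs(theta: np.ndarray, structure: str):
    """d(relative covariance)/d(theta_k) per level.

    Returns a list of (level, S_k) pairs aligned with theta's layout,
    where level is 0 (patient) or 1 (eye) and S_k the q x q derivative.
    """
    if structure == "nested_intercepts":
        return [(0, np.array([[2.0 * np.exp(2 * theta[0])]])),
                (1, np.array([[2.0 * np.exp(2 * theta[1])]]))]
    if structure == "patient_intercept":
        return [(0, np.array([[2.0 * np.exp(2 * theta[0])]]))]

    out = []
    for lvl, t in ((0, theta[:3]), (1, theta[3:])):
        L = np.array([[np.exp(t[0]), 0.0], [t[1], np.exp(t[2])]])
        dLs = (
            np.array([[np.exp(t[0]), 0.0], [0.0, 0.0]]),
            np.array([[0.0, 0.0], [1.0, 0.0]]),
            np.array([[0.0, 0.0], [0.0, np.exp(t[2])]]),
        )
        for dL in dLs:
            out.append((lvl, dL @ L.T + L @ dL.T))
    return out


def _reml_value_and_grad(theta, cs: "ClusterSet", groups, n_obs):
    """REML criterion and its analytic gradient in one pass.

    Uses the envelope theorem: at the profiled GLS beta and residual
    variance, only the explicit dependence of log|W|, log|X'W^-1 X| and
    the weighted RSS on the covariance parameters contributes.
    """
    Dp, De = _theta_to_cov(theta, cs.structure)
    p = cs.p
    qp = cs.qp
    qe = cs.qe
    logW = 0.0
    A = np.zeros((p, p))
    b = np.zeros(p)
    yy = 0.0
    stash = []
    for g in groups:
        B = g.XY.shape[0]
        nz = qp + (0 if g.Ze is None else g.Ze.shape[2])
        if cs.shared_w:
            W = np.eye(g.n) + Dp[0, 0] * g.Jp
            if g.Je is not None:
                W = W + De[0, 0] * g.Je
            Winv = np.linalg.inv(W)
            logW += B * float(np.linalg.slogdet(W)[1])
            rhs = g.XY.transpose(1, 0, 2).reshape(g.n, -1)
            sol = (Winv @ rhs).reshape(g.n, B, p + 1).transpose(1, 0, 2)
            # Z is data-independent here: one solve serves the whole batch
            Z0 = np.concatenate(
                [g.Zp[0]] + ([] if g.Ze is None else [g.Ze[0]]), axis=1)
            solZ = np.broadcast_to(Winv @ Z0, (B, g.n, nz))
        else:
            W = np.broadcast_to(np.eye(g.n), (B, g.n, g.n)).copy()
            W += (g.Zp @ Dp) @ g.Zp.transpose(0, 2, 1)
            if g.Ze is not None:
                E = g.Ze.shape[2] // De.shape[0]
                Dblock = np.kron(np.eye(E), De)
                W += (g.Ze @ Dblock) @ g.Ze.transpose(0, 2, 1)
            Lb = np.linalg.cholesky(W)
            logW += 2.0 * float(
                np.log(np.diagonal(Lb, axis1=1, axis2=2)).sum())
            Zfull = (g.Zp if g.Ze is None
                     else np.concatenate([g.Zp, g.Ze], axis=2))
            big = np.concatenate([g.XY, Zfull], axis=2)
            sol_all = np.linalg.solve(W, big)
            sol = sol_all[:, :, :p + 1]
            solZ = sol_all[:, :, p + 1:]
        Xflat = g.X.reshape(-1, p)
        solflat = sol.reshape(-1, p + 1)
        A += Xflat.T @ solflat[:, :p]
        b += Xflat.T @ solflat[:, p]
        yy += float(g.y.reshape(-1) @ solflat[:, p])
        stash.append((g, sol, solZ))

    Ainv = np.linalg.inv(A)
    beta = Ainv @ b
    rss = max(yy - float(b @ beta), 1e-300)
    df_resid = n_obs - p
    sigma2 = max(rss / df_resid, 1e-30)
    logdetA = float(np.linalg.slogdet(A)[1])
    crit = df_resid * (_LOG_2PI + 1.0 + np.log(sigma2)) + logW + logdetA

    kappa = df_resid / rss

    # accumulate the per-level q x q matrices M = sum_i [Z'W^-1 Z
    #   - kappa (Z'r~)(Z'r~)' - (Z'X~) A^-1 (X~'Z)]
    Mp = np.zeros((qp, qp))
    Me = np.zeros((qe, qe)) if qe else None
    for g, sol, solZ in stash:
        Xs = sol[:, :, :p]
        rs = sol[:, :, p] - np.einsum("bnj,j->bn", Xs, beta)
        Zfull = (g.Zp if g.Ze is None
                 else np.concatenate([g.Zp, g.Ze], axis=2))
        ZtWZ = np.einsum("bni,bnj->bij", Zfull, solZ)
        a = np.einsum("bni,bn->bi", Zfull, rs)
        P = np.einsum("bni,bnj->bij", Zfull, Xs)
        G = (ZtWZ.sum(axis=0)
             - kappa * np.einsum("bi,bj->ij", a, a)
             - np.einsum("bij,jk,blk->il", P, Ainv, P))
        Mp += G[:qp, :qp]
        if qe:
            nE = (Zfull.shape[2] - qp) // qe
            for e in range(nE):
                s = qp + e * qe
                Me += G[s:s + qe, s:s + qe]

    derivs = _cov_derivs(theta, cs.structure)
    grad = np.array([
        float((S * (Mp if lvl == 0 else Me)).sum()) for lvl, S in derivs
    ])
    return crit, grad, _Profile(crit, beta, sigma2, A)


def _reml_profile(theta, cs: ClusterSet, groups, n_obs) -> _Profile:
    Dp, De = _theta_to_cov(theta, cs.structure)
    p = cs.p
    logW = 0.0
    A = np.zeros((p, p))
    b = np.zeros(p)
    yy = 0.0
    for g in groups:
        B = g.XY.shape[0]
        if cs.shared_w:
            W = np.eye(g.n) + Dp[0, 0] * g.Jp
            if g.Je is not None:
                W = W + De[0, 0] * g.Je
            Winv = np.linalg.inv(W)
            logW += B * float(np.linalg.slogdet(W)[1])
            rhs = g.XY.transpose(1, 0, 2).reshape(g.n, -1)
            sol = (Winv @ rhs).reshape(g.n, B, p + 1).transpose(1, 0, 2)
        else:
            W = np.broadcast_to(np.eye(g.n), (B, g.n, g.n)).copy()
            W += (g.Zp @ Dp) @ g.Zp.transpose(0, 2, 1)
            if g.Ze is not None:
                E = g.Ze.shape[2] // De.shape[0]
                Dblock = np.kron(np.eye(E), De)
                W += (g.Ze @ Dblock) @ g.Ze.transpose(0, 2, 1)
            _, ld = np.linalg.slogdet(W)
            logW += ld.sum()
            sol = np.linalg.solve(W, g.XY)
        Xflat = g.X.reshape(-1, p)
        solflat = sol.reshape(-1, p + 1)
        A += Xflat.T @ solflat[:, :p]
        b += Xflat.T @ solflat[:, p]
        yy += float(g.y.reshape(-1) @ solflat[:, p])
    beta = np.linalg.solve(A, b)
    rss = max(yy - float(b @ beta), 0.0)
    df_resid = n_obs - p
    sigma2 = max(rss / df_resid, 1e-30)
    logdetA = float(np.linalg.slogdet(A)[1])
    crit = df_resid * (_LOG_2PI + 1.0 + np.log(sigma2)) + logW + logdetA
    return _Profile(crit, beta, sigma2, A)


def _start_candidates(structure: str, theta0, rng) -> list[np.ndarray]:
    """Coarse start points; the REML surface is flat once variances hit ~0,
    so a single descent from an arbitrary start can stall on the boundary."""
    cands: list[np.ndarray] = []
    if theta0 is not None:
        cands.append(np.asarray(theta0, float))
    cands.append(_theta_init(structure))
    if structure in ("nested_intercepts", "patient_intercept"):
        grid = [-2.0, -1.0, -0.3, 0.3, 1.0]
        if structure == "patient_intercept":
            cands.extend(np.array([g]) for g in grid)
        else:
            cands.extend(np.array([a, b]) for a in grid for b in grid)
    else:
        diag = [-1.6, -0.7, 0.0, 0.7]
        for a in diag:
            for b in diag:
                cands.append(np.array([a, 0.0, b - 1.2, a, 0.0, b - 1.2]))
        cands.extend(
            rng.uniform([-2.5, -0.5, -3.0, -2.5, -0.5, -3.0],
                        [1.0, 0.5, 0.5, 1.0, 0.5, 0.5]) for _ in range(6)
        )
    return cands


def _optimize_reml(cs: ClusterSet, groups, n_obs, theta0=None, max_iter=100,
                   n_restarts=5, rng=None, tol=1e-10, warm_only=False):
    """Minimize the -2 restricted log-likelihood over theta.

    Strategy: rank coarse start candidates by criterion value, run bounded
    quasi-Newton from the best few, then polish the winner with a simplex
    search (robust to the flat log-scale boundary region). With
    ``warm_only`` (bootstrap refits) the coarse search is skipped and the
    descent starts from the supplied ``theta0``.
    """
    structure = cs.structure
    bounds = _theta_bounds(structure)
    rng = np.random.default_rng(0) if rng is None else rng

    def fun(t):
        return _reml_profile(t, cs, groups, n_obs).crit

    def fun_grad(t):
        c, g, _ = _reml_value_and_grad(t, cs, groups, n_obs)
        return c, g

    if warm_only and theta0 is not None:
        # bootstrap refit: single descent from the full-data optimum
        res = minimize(fun_grad, np.asarray(theta0, float), method="L-BFGS-B",
                       jac=True, bounds=bounds,
                       options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8})
        if not res.success:
            alt = minimize(fun, np.asarray(theta0, float), method="Nelder-Mead",
                           options={"maxiter": 150 * len(bounds),
                                    "xatol": 1e-6, "fatol": 1e-8})
            if alt.fun < res.fun or not res.success:
                res = alt
        res.x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
        return res

    cands = _start_candidates(structure, theta0, rng)
    scored = sorted(((fun(t), i) for i, t in enumerate(cands)), key=lambda x: x[0])
    n_starts = max(1, min(1 + n_restarts, 2))
    best = None
    for _, i in scored[:n_starts]:
        res = minimize(fun_grad, cands[i], method="L-BFGS-B", jac=True,
                       bounds=bounds,
                       options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-7})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    polish = minimize(fun, best.x, method="Nelder-Mead",
                      options={"maxiter": 60 * len(best.x), "xatol": 1e-6,
                               "fatol": 1e-8})
    if polish.fun < best.fun:
        out = polish
    else:
        out = best
    out.x = np.clip(out.x, [b[0] for b in bounds], [b[1] for b in bounds])
    if not out.success and (best.success or polish.success):
        out.success = True
    return out


# ---------------------------------------------------------------------------
# Public fit result
# ---------------------------------------------------------------------------


@dataclass
class LMMFit:
    """Result of one REML fit.

    Variance components are on the response scale (µm / µm-per-year). For
    intercept structures ``vc`` carries per-level variances; for
    intercept+slope structures it carries the per-level 2x2 covariance
    matrices (order: intercept, years-slope).
    """

    spec: ModelSpec
    term_names: tuple[str, ...]
    fe_params: np.ndarray
    fe_bse: np.ndarray
    fe_vcov: np.ndarray
    vc: dict = field(default_factory=dict)
    sigma2: float = np.nan
    loglik: float = np.nan
    converged: bool = False
    boundary: bool = False
    n_obs: int = 0
    n_patients: int = 0
    n_eyes: int = 0
    theta: np.ndarray | None = None

    @property
    def neg2_reml(self) -> float:
        return -2.0 * self.loglik

    def term_index(self, term: str) -> int:
        try:
            return self.term_names.index(term)
        except ValueError:
            raise KeyError(
                f"term {term!r} not in model (terms: {self.term_names})"
            ) from None

    def containment_df(self, term: str) -> int:
        # The intercept is tested at the observation level but not counted
        # in any level's estimated-term tally (nlme's bookkeeping).
        lvl = _TERM_LEVEL[term]
        nonint = [t for t in self.term_names if t != "intercept"]
        p1 = sum(1 for t in nonint if _TERM_LEVEL[t] == 1)
        p2 = sum(1 for t in nonint if _TERM_LEVEL[t] == 2)
        p3 = sum(1 for t in nonint if _TERM_LEVEL[t] == 3)
        if self.spec.random_structure == "patient_intercept":
            # two levels only: patient, observation
            if lvl == 1:
                return self.n_patients - 1 - p1
            return self.n_obs - self.n_patients - (p2 + p3)
        if lvl == 1:
            return self.n_patients - 1 - p1
        if lvl == 2:
            return self.n_eyes - self.n_patients - p2
        return self.n_obs - self.n_eyes - p3

    def to_dict(self) -> dict:
        vc = {}
        for k, v in self.vc.items():
            vc[k] = np.asarray(v).tolist() if np.ndim(v) else float(v)
        return {
            "response": self.spec.response,
            "fixed_terms": list(self.term_names),
            "random_structure": self.spec.random_structure,
            "fe_params": self.fe_params.tolist(),
            "fe_bse": self.fe_bse.tolist(),
            "fe_vcov": self.fe_vcov.tolist(),
            "variance_components": vc,
            "sigma2": float(self.sigma2),
            "loglik_reml": float(self.loglik),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "n_obs": int(self.n_obs),
            "n_patients": int(self.n_patients),
            "n_eyes": int(self.n_eyes),
        }


class WaldResult(NamedTuple):
    estimate: float
    se: float
    t: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


def _build_design(data: pd.DataFrame, terms: Sequence[str],
                  years_col: str, group_col: str, eye_col: str) -> np.ndarray:
    n = len(data)
    cols = []
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(n))
        elif t == "years":
            cols.append(data[years_col].to_numpy(float))
        elif t == "group":
            cols.append((data[group_col].to_numpy() == "stgd1").astype(float))
        elif t == "laterality":
            cols.append((data[eye_col].to_numpy() == "OS").astype(float))
        elif t == "years:group":
            cols.append(
                data[years_col].to_numpy(float)
                * (data[group_col].to_numpy() == "stgd1").astype(float)
            )
    return np.column_stack(cols)


class NestedMixedModel(BaseEstimator):
    """REML linear mixed model with patient / eye-within-patient random effects.

    Parameters
    ----------
    fixed_terms : tuple of str
        Fixed-effect terms; see :class:`ModelSpec`.
    random_structure : str
        ``"nested_intercepts"``, ``"nested_intercept_slope"`` or
        ``"patient_intercept"``.
    response : str
        Response column in the fitted DataFrame.
    max_iter : int
        Outer iteration cap for the bounded quasi-Newton search.
    n_restarts : int
        Jittered restarts attempted when the search does not converge.
    drop_constant_terms : bool
        Silently drop non-intercept terms whose column is constant (e.g.
        a years term when every observation is a baseline scan) instead of
        failing on a rank-deficient design.

    Attributes
    ----------
    result_ : LMMFit
        Full fit result.
    fe_params_ : ndarray
        Fixed-effect estimates, ordered as ``term_names_``.
    converged_ : bool
    """

    def __init__(self, fixed_terms=("intercept",), random_structure="nested_intercepts",
                 response="thickness_um", max_iter=100, n_restarts=5,
                 drop_constant_terms=False,
                 patient_col="patient_id", eye_col="eye",
                 years_col="years_since_baseline", group_col="group"):
        self.fixed_terms = fixed_terms
        self.random_structure = random_structure
        self.response = response
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.drop_constant_terms = drop_constant_terms
        self.patient_col = patient_col
        self.eye_col = eye_col
        self.years_col = years_col
        self.group_col = group_col

    # ------------------------------------------------------------------
    def _spec(self) -> ModelSpec:
        return ModelSpec(self.response, tuple(self.fixed_terms), self.random_structure)

    def fit(self, X: pd.DataFrame, y=None) -> "NestedMixedModel":
        """Fit by REML. ``X`` is a long-format DataFrame; ``y`` is ignored."""
        spec = self._spec()
        data = X
        required = {self.patient_col, spec.response}
        if self.random_structure != "patient_intercept":
            required.add(self.eye_col)
        needs_years = ("years" in spec.fixed_terms
                       or "years:group" in spec.fixed_terms
                       or self.random_structure == "nested_intercept_slope")
        if needs_years:
            required.add(self.years_col)
        missing = sorted(required - set(data.columns))
        if missing:
            raise ValueError(f"missing required columns: {missing}")

        data = data.loc[data[spec.response].notna()]
        yv = data[spec.response].to_numpy(float)
        terms = list(spec.fixed_terms)
        years = (data[self.years_col].to_numpy(float)
                 if self.years_col in data.columns else np.zeros(len(data)))
        Xd = _build_design(data, terms, self.years_col, self.group_col, self.eye_col)

        if self.drop_constant_terms:
            keep = [0] + [j for j in range(1, Xd.shape[1])
                          if np.ptp(Xd[:, j]) > 0]
            if len(keep) < Xd.shape[1]:
                dropped = [terms[j] for j in range(len(terms)) if j not in keep]
                warnings.warn(f"dropping constant fixed terms: {dropped}")
                terms = [terms[j] for j in keep]
                Xd = Xd[:, keep]

        # rank check with pivoted QR so aliased terms can be named
        _, Rm = np.linalg.qr(Xd, mode="reduced")
        diag = np.abs(np.diag(Rm))
        if diag.min() <= 1e-10 * max(diag.max(), 1.0):
            from scipy.linalg import qr as _qr
            _, Rp, piv = _qr(Xd, mode="economic", pivoting=True)
            dg = np.abs(np.diag(Rp))
            rank = int((dg > 1e-10 * max(dg.max(), 1.0)).sum())
            aliased = [terms[j] for j in piv[rank:]]
            raise ValueError(f"rank-deficient fixed design; aliased terms: {aliased}")

        pat_codes = pd.factorize(data[self.patient_col].to_numpy())[0]
        if self.random_structure == "patient_intercept":
            eye_codes = np.zeros(len(data), dtype=int)
        else:
            eye_key = (data[self.patient_col].astype(str) + "|"
                       + data[self.eye_col].astype(str)).to_numpy()
            eye_codes = pd.factorize(eye_key)[0]

        cs = ClusterSet(yv, Xd, years, pat_codes, eye_codes, self.random_structure)
        if cs.n_patients < 2:
            raise ValueError("need at least 2 patients (clusters) to fit random effects")
        if self.random_structure != "patient_intercept" and cs.n_eyes < 2:
            raise ValueError("need at least 2 eyes for the eye-level random effect")

        self.result_ = _fit_cluster_set(cs, spec, tuple(terms),
                                        max_iter=self.max_iter,
                                        n_restarts=self.n_restarts)
        self.term_names_ = self.result_.term_names
        self.fe_params_ = self.result_.fe_params
        self.fe_bse_ = self.result_.fe_bse
        self.converged_ = self.result_.converged
        self.n_features_in_ = Xd.shape[1]
        return self

    # convenience accessors -------------------------------------------------
    def wald(self, term: str) -> WaldResult:
        return wald_inference(self.result_, term)

    def group_profiles(self, average_laterality: bool = False) -> dict:
        return estimate_group_profiles(self.result_, average_laterality)


def _fit_cluster_set(cs: ClusterSet, spec: ModelSpec, term_names,
                     max_iter=100, n_restarts=5, theta0=None,
                     warm_only=False) -> LMMFit:
    groups = cs.full_groups()
    res = _optimize_reml(cs, groups, cs.n_obs, theta0=theta0,
                         max_iter=max_iter, n_restarts=n_restarts,
                         warm_only=warm_only)
    prof = _reml_profile(res.x, cs, groups, cs.n_obs)
    sigma2 = prof.sigma2
    Dp, De = _theta_to_cov(res.x, cs.structure)

    vc: dict = {}
    boundary = False
    if cs.structure == "nested_intercepts":
        vc = {
            "var_patient_intercept": sigma2 * Dp[0, 0],
            "var_eye_intercept": sigma2 * De[0, 0],
            "var_residual": sigma2,
        }
        boundary = min(Dp[0, 0], De[0, 0]) < 1e-10
    elif cs.structure == "patient_intercept":
        vc = {"var_patient_intercept": sigma2 * Dp[0, 0], "var_residual": sigma2}
        boundary = Dp[0, 0] < 1e-10
    else:
        vc = {
            "cov_patient": sigma2 * Dp,
            "cov_eye": sigma2 * De,
            "var_residual": sigma2,
        }
        boundary = min(np.diag(Dp).min(), np.diag(De).min()) < 1e-10

    fe_vcov = sigma2 * np.linalg.inv(prof.A)
    fit = LMMFit(
        spec=spec,
        term_names=tuple(term_names),
        fe_params=prof.beta,
        fe_bse=np.sqrt(np.diag(fe_vcov)),
        fe_vcov=fe_vcov,
        vc=vc,
        sigma2=sigma2,
        loglik=-0.5 * prof.crit,
        converged=bool(res.success),
        boundary=boundary,
        n_obs=cs.n_obs,
        n_patients=cs.n_patients,
        n_eyes=cs.n_eyes,
        theta=np.asarray(res.x),
    )
    return fit


# ---------------------------------------------------------------------------
# Module-level operations (thin wrappers)
# ---------------------------------------------------------------------------


def fit_reml(data: pd.DataFrame, spec: ModelSpec, **kwargs) -> LMMFit:
    """Fit the mixed model described by ``spec`` to long-format data."""
    model = NestedMixedModel(
        fixed_terms=spec.fixed_terms,
        random_structure=spec.random_structure,
        response=spec.response,
        **kwargs,
    )
    model.fit(data)
    return model.result_


def wald_inference(fit: LMMFit, term: str) -> WaldResult:
    """Wald t-test for one fixed term with containment denominator df."""
    from scipy.stats import t as t_dist

    if not fit.converged:
        raise RuntimeError("cannot test terms of a non-converged fit")
    j = fit.term_index(term)
    est = float(fit.fe_params[j])
    se = float(fit.fe_bse[j])
    tval = est / se
    df = fit.containment_df(term)
    p = 2.0 * float(t_dist.sf(abs(tval), df)) if est != 0.0 else 1.0
    return WaldResult(est, se, tval, df, p)


def estimate_group_profiles(fit: LMMFit, average_laterality: bool = False) -> dict:
    """Per-group baseline mean and yearly slope with SEs and 95% CIs.

    The control baseline is the model intercept (evaluated at the OD
    laterality reference, or averaged over laterality when
    ``average_laterality`` is set); the STGD1 baseline adds the group
    effect. Slopes come from the years term and the years-by-group
    interaction. CIs are estimate ± 1.96 SE.
    """
    if not fit.converged:
        raise RuntimeError("cannot summarize a non-converged fit")
    if "group" not in fit.term_names:
        raise KeyError("model has no group term")

    p = len(fit.term_names)

    def contrast(terms_weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(p)
        for t, w in terms_weights.items():
            if t in fit.term_names:
                c[fit.term_names.index(t)] = w
        return c

    lat_w = 0.5 if (average_laterality and "laterality" in fit.term_names) else 0.0

    combos = {
        ("control", "baseline"): {"intercept": 1.0, "laterality": lat_w},
        ("stgd1", "baseline"): {"intercept": 1.0, "group": 1.0, "laterality": lat_w},
        ("control", "slope"): {"years": 1.0},
        ("stgd1", "slope"): {"years": 1.0, "years:group": 1.0},
    }
    out: dict = {}
    for (grp, what), tw in combos.items():
        if what == "slope" and "years" not in fit.term_names:
            continue
        c = contrast(tw)
        est = float(c @ fit.fe_params)
        se = float(np.sqrt(c @ fit.fe_vcov @ c))
        out.setdefault(grp, {})[what] = {
            "estimate": est,
            "se": se,
            "ci": (est - 1.96 * se, est + 1.96 * se),
        }
    return out
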