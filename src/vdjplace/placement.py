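"""Query placement: attachment likelihoods, AIC_c and Akaike weights.

A rearrangement hypothesis is a triple (V attachment branch, J attachment
branch, breakpoint).  The query columns 5' of the breakpoint are scored by
attaching the query mid-branch in the V reference tree, the rest in the J
tree.  By time reversibility, attaching one new tip to a fixed tree and
re-optimising only the three adjacent branch lengths (query pendant t_q,
parent side t_p, child side t_c) is a three-taxon problem: the inside and
outside partial-likelihood messages at the branch endpoints summarise the
whole rest of the tree, so the computation is independent of reference size
and exactly equals the full-tree attachment likelihood.

Each segment's likelihood profile along a single branch length t has the
closed form  sum_k W[col,k] * exp(lam_k t)  in the GTR eigenbasis, which the
numba kernels exploit: a Brent line search per length, cycled to
convergence (delta logL < 1e-6, max 50 cycles, lengths clamped to [0, 10]).

Model fitness is the small-sample Akaike criterion
AIC_c = -2 logL + 2k + 2k(k+1)/(n-k-1) with k = 7 (six branch lengths plus
the breakpoint; GTR parameters are fixed bundle-wide) and n the number of
scored columns.  Every model evaluated during a search receives an Akaike
weight exp(-0.5 (AIC_c - min AIC_c)) normalised over the evaluated set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .gtr import GTRModel, encode_sequence
from .phylo import compute_partials
from .reference import ReferenceBundle
from .trees import Tree

MAX_BLEN = 10.0
K_PARAMS = 7
_TINY = 1e-300


# -- numba kernels -----------------------------------------------------


@njit(cache=True, fastmath=True)
def _profile_eval(W: np.ndarray, lam: np.ndarray, t: float) -> float:
    """sum_col log( sum_k W[col,k] exp(lam_k t) ), clamped below."""
    e0 = math.exp(lam[0] * t)
    e1 = math.exp(lam[1] * t)
    e2 = math.exp(lam[2] * t)
    e3 = math.exp(lam[3] * t)
    tot = 0.0
    for c in range(W.shape[0]):
        s = W[c, 0] * e0 + W[c, 1] * e1 + W[c, 2] * e2 + W[c, 3] * e3
        if s < _TINY:
            s = _TINY
        tot += math.log(s)
    return tot


@njit(cache=True, fastmath=True)
def _brent_max(W: np.ndarray, lam: np.ndarray, lo: float, hi: float,
               xatol: float) -> tuple[float, float]:
    """Maximise the eigen-profile over t in [lo, hi] (bounded Brent)."""
    golden = 0.3819660112501051
    a, b = lo, hi
    x = w = v = a + golden * (b - a)
    fx = fw = fv = -_profile_eval(W, lam, x)
    d = 0.0
    e = 0.0
    for _ in range(80):
        m = 0.5 * (a + b)
        tol1 = xatol + 1e-10 * abs(x)
        tol2 = 2.0 * tol1
        if abs(x - m) <= tol2 - 0.5 * (b - a):
            break
        use_golden = True
        if abs(e) > tol1:
            r = (x - w) * (fx - fv)
            q = (x - v) * (fx - fw)
            p = (x - v) * q - (x - w) * r
            q = 2.0 * (q - r)
            if q > 0.0:
                p = -p
            q = abs(q)
            etemp = e
            e = d
            if abs(p) < abs(0.5 * q * etemp) and p > q * (a - x) and p < q * (b - x):
                d = p / q
                u = x + d
                if (u - a) < tol2 or (b - u) < tol2:
                    d = tol1 if x < m else -tol1
                use_golden = False
        if use_golden:
            e = (b - x) if x < m else (a - x)
            d = golden * e
        u = x + d if abs(d) >= tol1 else x + (tol1 if d > 0 else -tol1)
        fu = -_profile_eval(W, lam, u)
        if fu <= fx:
            if u < x:
                b = x
            else:
                a = x
            v, fv = w, fw
            w, fw = x, fx
            x, fx = u, fu
        else:
            if u < x:
                a = u
            else:
                b = u
            if fu <= fw or w == x:
                v, fv = w, fw
                w, fw = u, fu
            elif fu <= fv or v == x or v == w:
                v, fv = u, fu
    # the boundaries themselves are legitimate optima (zero-length branches)
    fa = -_profile_eval(W, lam, lo)
    if fa < fx:
        x, fx = lo, fa
    return x, -fx


@njit(cache=True, fastmath=True)
def _pmat(basis: np.ndarray, lam: np.ndarray, t: float) -> np.ndarray:
    P = np.empty((4, 4))
    e = np.empty(4)
    for k in range(4):
        e[k] = math.exp(lam[k] * t)
    for x in range(4):
        for y in range(4):
            s = 0.0
            for k in range(4):
                s += basis[x, y, k] * e[k]
            P[x, y] = s if s > 0.0 else 0.0
    return P


@njit(cache=True, fastmath=True)
def _attach_loglik(U, F, q, basis, lam, tq, tp, tc) -> float:
    """logL of one segment at fixed lengths (scale offsets not included)."""
    Pp = _pmat(basis, lam, tp)
    Pc = _pmat(basis, lam, tc)
    Pq = _pmat(basis, lam, tq)
    tot = 0.0
    for col in range(U.shape[0]):
        s = 0.0
        for x in range(4):
            a = 0.0
            for p in range(4):
                a += U[col, p] * Pp[p, x]
            b = 0.0
            for c in range(4):
                b += Pc[x, c] * F[col, c]
            qv = 1.0 if q[col] >= 4 else Pq[x, q[col]]
            s += a * b * qv
        if s < _TINY:
            s = _TINY
        tot += math.log(s)
    return tot


@njit(cache=True, fastmath=True)
def _optimize_attachment(U, F, q, basis, lam, t_p0, t_c0, t_q0,
                         tol, max_cycles, xatol):
    """Cycle Brent line searches over (t_q, t_p, t_c); returns logL + lengths."""
    ncols = U.shape[0]
    tp, tc, tq = t_p0, t_c0, t_q0
    cur = _attach_loglik(U, F, q, basis, lam, tq, tp, tc)
    Wk = np.empty((ncols, 4))
    for _ in range(max_cycles):
        prev = cur
        # --- t_q profile: W[col,k] = sum_x a[col,x] b[col,x] basis[x,qcol,k]
        Pp = _pmat(basis, lam, tp)
        Pc = _pmat(basis, lam, tc)
        const = 0.0
        m = 0
        for col in range(ncols):
            if q[col] >= 4:
                s = 0.0
                for x in range(4):
                    a = 0.0
                    for p in range(4):
                        a += U[col, p] * Pp[p, x]
                    b = 0.0
                    for c in range(4):
                        b += Pc[x, c] * F[col, c]
                    s += a * b
                const += math.log(s if s > _TINY else _TINY)
            else:
                for k in range(4):
                    Wk[m, k] = 0.0
                for x in range(4):
                    a = 0.0
                    for p in range(4):
                        a += U[col, p] * Pp[p, x]
                    b = 0.0
                    for c in range(4):
                        b += Pc[x, c] * F[col, c]
                    ab = a * b
                    for k in range(4):
                        Wk[m, k] += ab * basis[x, q[col], k]
                m += 1
        if m > 0:
            tq, best = _brent_max(Wk[:m], lam, 0.0, MAX_BLEN, xatol)
            cur = best + const
        # --- t_p profile: W[col,k] = sum_{p,x} U[col,p] basis[p,x,k] g[col,x]
        Pq = _pmat(basis, lam, tq)
        Pc = _pmat(basis, lam, tc)
        for col in range(ncols):
            for k in range(4):
                Wk[col, k] = 0.0
            for x in range(4):
                b = 0.0
                for c in range(4):
                    b += Pc[x, c] * F[col, c]
                qv = 1.0 if q[col] >= 4 else Pq[x, q[col]]
                g = b * qv
                for p in range(4):
                    ug = U[col, p] * g
                    for k in range(4):
                        Wk[col, k] += ug * basis[p, x, k]
        tp, cur = _brent_max(Wk, lam, 0.0, MAX_BLEN, xatol)
        # --- t_c profile: W[col,k] = sum_{x,c} h[col,x] basis[x,c,k] F[col,c]
        Pp = _pmat(basis, lam, tp)
        for col in range(ncols):
            for k in range(4):
                Wk[col, k] = 0.0
            for x in range(4):
                a = 0.0
                for p in range(4):
                    a += U[col, p] * Pp[p, x]
                qv = 1.0 if q[col] >= 4 else Pq[x, q[col]]
                h = a * qv
                for c in range(4):
                    hf = h * F[col, c]
                    for k in range(4):
                        Wk[col, k] += hf * basis[x, c, k]
        tc, cur = _brent_max(Wk, lam, 0.0, MAX_BLEN, xatol)
        if cur - prev < tol:
            break
    return cur, tq, tp, tc


# -- model containers --------------------------------------------------


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"segment too short to score: n={n} <= k+1={k + 1}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class AttachmentModel:
    v_branch: int
    j_branch: int
    breakpoint: int
    logL: float
    fitted_lengths: tuple  # (tq_v, tp_v, tc_v, tq_j, tp_j, tc_j)
    k: int
    n: int
    aicc: float
    weight: float = 0.0


@dataclass
class ModelPopulation:
    models: list  # list[AttachmentModel], distinct by (v, j, breakpoint)
    best_aicc: float
    converged: bool
    generations: int
    seed: int
    n_evaluated: int = 0

    @property
    def best(self) -> AttachmentModel:
        return min(self.models, key=lambda m: m.aicc)


def akaike_weights(models: list) -> list:
    """Normalised Akaike weights over all (finite-AIC_c) models, in place."""
    if not models:
        raise ValueError("no models to weight")
    finite = [m for m in models if math.isfinite(m.aicc)]
    if not finite:
        raise ValueError("no model with finite AIC_c")
    amin = min(m.aicc for m in finite)
    total = 0.0
    for m in models:
        m.weight = math.exp(-0.5 * (m.aicc - amin)) if math.isfinite(m.aicc) else 0.0
        total += m.weight
    for m in models:
        m.weight /= total
    return models


# -- engine ------------------------------------------------------------


class RegionPlacement:
    """Attachment scoring for one region tree (V or J)."""

    def __init__(self, tree: Tree, alignment, model: GTRModel):
        self.tree = tree
        self.model = model
        self.ncols = alignment.column_count
        states = np.full((tree.n_nodes, self.ncols), 4, dtype=np.int8)
        index = tree.leaf_index()
        for name in alignment.rows:
            states[index[name]] = alignment.encoded(name)
        parts = compute_partials(tree, states, model)
        self.branches = [int(b) for b in tree.branches]
        self.branch_labels = {b: tree.labels[b] for b in self.branches}
        self.parent_labels = {
            b: tree.labels[tree.parent[b]] for b in self.branches
        }
        self._U = {b: np.ascontiguousarray(parts.U[b]) for b in self.branches}
        self._F = {b: np.ascontiguousarray(parts.F[b]) for b in self.branches}
        self._off = {
            b: float((parts.logscale_U[b] + parts.logscale_F[b]).sum())
            for b in self.branches
        }
        self._basis = np.ascontiguousarray(model.basis)
        self._lam = np.ascontiguousarray(model.eigvals)

    def attach(
        self,
        branch: int,
        qstates: np.ndarray,
        tol: float = 1e-6,
        max_cycles: int = 50,
        xatol: float = 1e-5,
    ) -> tuple[float, float, float, float]:
        """Optimised attachment logL on one branch; returns (logL, tq, tp, tc)."""
        half = max(float(self.tree.blen[branch]) / 2.0, 1e-8)
        logL, tq, tp, tc = _optimize_attachment(
            self._U[branch], self._F[branch], qstates,
            self._basis, self._lam, half, half, 0.02, tol, max_cycles, xatol,
        )
        return logL + self._off[branch], tq, tp, tc

    def loglik(self, branch: int, qstates: np.ndarray,
               tq: float, tp: float, tc: float) -> float:
        """Attachment logL at fixed lengths (for oracles and diagnostics)."""
        return float(
            _attach_loglik(
                self._U[branch], self._F[branch], qstates,
                self._basis, self._lam, tq, tp, tc,
            )
        ) + self._off[branch]


class PlacementEngine:
    """Scores (v_branch, j_branch, breakpoint) models for one mapped query."""

    def __init__(self, bundle: ReferenceBundle):
        self.bundle = bundle
        self.v = RegionPlacement(bundle.v_tree, bundle.v_alignment, bundle.v_model)
        self.j = RegionPlacement(bundle.j_tree, bundle.j_alignment, bundle.j_model)

    def prepare_query(self, query: str, qcols: np.ndarray) -> "QueryData":
        return QueryData(self, query, qcols)


class QueryData:
    """Per-query column/state bookkeeping shared across all models."""

    def __init__(self, engine: PlacementEngine, query: str, qcols: np.ndarray):
        self.engine = engine
        vC = engine.v.ncols
        jC = engine.j.ncols
        enc = encode_sequence(query)
        # per region column: query position mapped there (-1) and its state
        self.v_qpos = np.full(vC, -1, dtype=np.int64)
        self.v_qstate = np.full(vC, 4, dtype=np.int8)
        self.j_qpos = np.full(jC, -1, dtype=np.int64)
        self.j_qstate = np.full(jC, 4, dtype=np.int8)
        for qpos, col in enumerate(qcols):
            if col < 0:
                continue
            if col < vC:
                self.v_qpos[col] = qpos
                self.v_qstate[col] = enc[qpos]
            else:
                self.j_qpos[col - vC] = qpos
                self.j_qstate[col - vC] = enc[qpos]
        self.n_scored = int(
            np.sum((self.v_qpos >= 0) & (self.v_qstate < 4))
            + np.sum((self.j_qpos >= 0) & (self.j_qstate < 4))
        )
        self._vcache: dict[tuple[int, int], tuple] = {}
        self._jcache: dict[tuple[int, int], tuple] = {}

    def v_states(self, breakpoint: int) -> np.ndarray:
        out = self.v_qstate.copy()
        out[(self.v_qpos < 0) | (self.v_qpos >= breakpoint)] = 4
        return out

    def j_states(self, breakpoint: int) -> np.ndarray:
        out = self.j_qstate.copy()
        out[(self.j_qpos < 0) | (self.j_qpos < breakpoint)] = 4
        return out

    def score(self, v_branch: int, j_branch: int, breakpoint: int) -> AttachmentModel:
        """Evaluate one rearrangement hypothesis (cached per segment)."""
        key_v = (v_branch, breakpoint)
        if key_v not in self._vcache:
            self._vcache[key_v] = self.engine.v.attach(
                v_branch, self.v_states(breakpoint)
            )
        key_j = (j_branch, breakpoint)
        if key_j not in self._jcache:
            self._jcache[key_j] = self.engine.j.attach(
                j_branch, self.j_states(breakpoint)
            )
        lv, tqv, tpv, tcv = self._vcache[key_v]
        lj, tqj, tpj, tcj = self._jcache[key_j]
        logL = lv + lj
        if not math.isfinite(logL):
            raise FloatingPointError("non-finite attachment likelihood")
        return AttachmentModel(
            v_branch=v_branch, j_branch=j_branch, breakpoint=breakpoint,
            logL=logL, fitted_lengths=(tqv, tpv, tcv, tqj, tpj, tcj),
            k=K_PARAMS, n=self.n_scored,
            aicc=aicc(logL, K_PARAMS, self.n_scored),
        )
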