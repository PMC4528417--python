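"""Phylogenetic likelihood on fixed topologies.

Implements Felsenstein's pruning algorithm with per-column log scaling,
the matching outside (root-to-tip) messages, coordinate-wise maximum
likelihood branch-length optimisation and GTR parameter fitting on a fixed
tree.  The inside/outside decomposition is the workhorse of the whole
package: for any branch e = (parent P, child C),

    L = sum_p U_e[p] * sum_c P_t(p,c) * F_C[c]

per column, where F_C is the inside partial below C and U_e collects the
outside message at P times the inside messages of C's siblings.  Query
placement reuses exactly these arrays (see placement module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .gtr import GTRModel, MISSING, NSTATES, empirical_frequencies
from .trees import Tree

_TINY = 1e-300
MAX_BLEN = 10.0


def compress_columns(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical alignment columns; returns (unique_states, weights)."""
    uniq, inv, counts = np.unique(
        states.T, axis=0, return_inverse=True, return_counts=True
    )
    return uniq.T.copy(), counts.astype(float)


@dataclass
class Partials:
    """Scaled inside (F) and outside (U) messages for every node/branch."""

    F: np.ndarray        # (n_nodes, ncols, 4) inside, scaled per (node, col)
    logscale_F: np.ndarray   # (n_nodes, ncols)
    U: np.ndarray        # (n_nodes, ncols, 4) outside message for branch above node
    logscale_U: np.ndarray   # (n_nodes, ncols)


def _rescale(arr: np.ndarray, logscale: np.ndarray) -> None:
    m = arr.max(axis=1)
    m[m <= 0] = 1.0
    arr /= m[:, None]
    logscale += np.log(m)


def inside_partials(
    tree: Tree, states: np.ndarray, model: GTRModel
) -> tuple[np.ndarray, np.ndarray]:
    """Inside (pruning) partial likelihoods for all nodes.

    ``states`` is (n_nodes, ncols) int8; only leaf rows are read, code 4 is
    missing data.
    """
    n, ncols = states.shape
    F = np.empty((n, ncols, NSTATES))
    ls = np.zeros((n, ncols))
    for i in tree.postorder:
        if tree.is_leaf(i):
            s = states[i]
            Fi = np.zeros((ncols, NSTATES))
            obs = s < NSTATES
            Fi[obs, s[obs]] = 1.0
            Fi[~obs, :] = 1.0
            F[i] = Fi
            continue
        acc = np.ones((ncols, NSTATES))
        scale = np.zeros(ncols)
        for c in tree.children[i]:
            P = model.transition(tree.blen[c])
            acc *= F[c] @ P.T
            scale += ls[c]
        _rescale(acc, scale)
        F[i] = acc
        ls[i] = scale
    return F, ls


def outside_partials(
    tree: Tree, F: np.ndarray, ls_F: np.ndarray, model: GTRModel
) -> tuple[np.ndarray, np.ndarray]:
    """Outside messages U_e for the branch above every non-root node."""
    n, ncols, _ = F.shape
    U = np.zeros((n, ncols, NSTATES))
    ls_U = np.zeros((n, ncols))
    # O[i]: message arriving at node i from above (root prior for the root)
    O = np.zeros((n, ncols, NSTATES))
    ls_O = np.zeros((n, ncols))
    O[tree.root] = model.pi[None, :]
    for i in reversed(tree.postorder):  # preorder
        if tree.is_leaf(i) and i != tree.root:
            pass
        for c in tree.children[i]:
            acc = O[i].copy()
            scale = ls_O[i].copy()
            for s in tree.children[i]:
                if s == c:
                    continue
                Ps = model.transition(tree.blen[s])
                acc = acc * (F[s] @ Ps.T)
                scale = scale + ls_F[s]
            _rescale(acc, scale)
            U[c] = acc
            ls_U[c] = scale
            Pc = model.transition(tree.blen[c])
            Oc = acc @ Pc
            sc = scale.copy()
            _rescale(Oc, sc)
            O[c] = Oc
            ls_O[c] = sc
    return U, ls_U


def compute_partials(tree: Tree, states: np.ndarray, model: GTRModel) -> Partials:
    F, lsF = inside_partials(tree, states, model)
    U, lsU = outside_partials(tree, F, lsF, model)
    return Partials(F=F, logscale_F=lsF, U=U, logscale_U=lsU)


def tree_loglik(
    tree: Tree,
    states: np.ndarray,
    model: GTRModel,
    weights: np.ndarray | None = None,
) -> float:
    F, ls = inside_partials(tree, states, model)
    site = np.log(np.maximum(F[tree.root] @ model.pi, _TINY)) + ls[tree.root]
    if not np.all(np.isfinite(site)):
        raise FloatingPointError("non-finite likelihood")
    if weights is None:
        return float(site.sum())
    return float(site @ weights)


def _branch_profile(
    tree: Tree, node: int, parts: Partials, model: GTRModel
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column eigen-profile W so that L_col(t) = sum_k W[col,k] e^(lam_k t)."""
    W = np.einsum("np,pck,nc->nk", parts.U[node], model.basis, parts.F[node])
    off = parts.logscale_U[node] + parts.logscale_F[node]
    return W, off


def optimize_branch_lengths(
    tree: Tree,
    states: np.ndarray,
    model: GTRModel,
    weights: np.ndarray | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> list[float]:
    """Coordinate-ascent ML branch lengths on the fixed topology (in place).

    Returns the log-likelihood after each sweep; the sequence is
    non-decreasing (each univariate step is solved exactly with fresh
    partials).
    """
    w = np.ones(states.shape[1]) if weights is None else weights
    history = [tree_loglik(tree, states, model, w)]
    for _ in range(max_sweeps):
        for b in tree.branches:
            parts = compute_partials(tree, states, model)
            W, off = _branch_profile(tree, b, parts, model)

            def neg(t: float) -> float:
                site = np.maximum(W @ np.exp(model.eigvals * t), _TINY)
                return -float((np.log(site) + off) @ w)

            res = minimize_scalar(
                neg, bounds=(0.0, MAX_BLEN), method="bounded",
                options={"xatol": 1e-9},
            )
            if -res.fun >= -neg(tree.blen[b]):
                tree.blen[b] = float(res.x)
        history.append(tree_loglik(tree, states, model, w))
        if history[-1] - history[-2] < tol:
            break
    return history


def fit_gtr(
    tree: Tree,
    states: np.ndarray,
    weights: np.ndarray | None = None,
    fix_rates: bool = False,
    tol: float = 1e-6,
    max_rounds: int = 10,
) -> tuple[GTRModel, list[float]]:
    """Fit GTR exchangeabilities + branch lengths on a fixed topology.

    Base frequencies are empirical; exchangeabilities (GT fixed to 1) are
    optimised by quasi-Newton search in log space, alternating with
    branch-length sweeps.  Returns the fitted model and the (non-decreasing)
    log-likelihood trace.
    """
    if sum(1 for i in tree.leaves) < 3:
        raise ValueError("need at least 3 sequences to fit the reference model")
    leaf_rows = states[tree.leaves]
    pi = empirical_frequencies(leaf_rows)
    model = GTRModel(rates=np.ones(6), pi=pi)
    history = [tree_loglik(tree, states, model, weights)]
    for _ in range(max_rounds):
        hist = optimize_branch_lengths(tree, states, model, weights, tol=tol)
        history.extend(hist[1:])
        if not fix_rates:
            def neg(x: np.ndarray) -> float:
                rates = np.append(np.exp(x), 1.0)
                try:
                    return -tree_loglik(tree, states, GTRModel(rates, pi), weights)
                except FloatingPointError:
                    return 1e12

            x0 = np.log(np.maximum(model.rates[:5], 1e-6))
            res = minimize(neg, x0, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400})
            if -res.fun > history[-1]:
                model = GTRModel(np.append(np.exp(res.x), 1.0), pi)
                history.append(-res.fun)
        if len(history) >= 2 and history[-1] - history[-2] < tol:
            if fix_rates:
                break
            # one more branch sweep already converged too?
            if hist[-1] - hist[0] < tol:
                break
    if not np.isfinite(history[-1]):
        raise FloatingPointError("non-finite likelihood in reference fit")
    return model, history
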