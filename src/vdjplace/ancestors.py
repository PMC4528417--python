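"""Joint maximum-likelihood ancestral sequence reconstruction.

Implements the max-product (Viterbi-style) dynamic programme over internal
node states: for each alignment column the jointly most likely assignment of
states to all internal nodes is found by a postorder max/argmax pass and a
preorder traceback.  Ties are broken deterministically by the fixed
nucleotide order A < C < G < T.  A node is reconstructed as a gap in a
column only when every descendant leaf is gapped there, so ancestor
sequences live in the same coordinates as the reference alignment.
"""

from __future__ import annotations

import numpy as np

from .gtr import CODE_TO_BASE, GTRModel, MISSING, NSTATES
from .trees import Tree

_NEG = -1e30


def reconstruct_ancestors(
    tree: Tree, states: np.ndarray, model: GTRModel
) -> dict[int, np.ndarray]:
    """Joint-ML states for every internal node.

    ``states`` is (n_nodes, ncols) int8 with leaf rows observed (4 = missing).
    Returns a map internal-node-id -> (ncols,) int8 array (4 where the whole
    clade is gapped).
    """
    n, ncols = states.shape
    with np.errstate(divide="ignore"):
        logP = {
            b: np.log(np.maximum(model.transition(tree.blen[b]), 0.0))
            for b in tree.branches
        }
        logpi = np.log(model.pi)

    # L[i][col, p] = best log-prob of the subtree below i given parent state p
    L = np.full((n, ncols, NSTATES), 0.0)
    choice = np.zeros((n, ncols, NSTATES), dtype=np.int8)
    all_gap = np.zeros((n, ncols), dtype=bool)

    for i in tree.postorder:
        if tree.is_leaf(i):
            s = states[i]
            all_gap[i] = s == MISSING
            Li = np.full((ncols, NSTATES), _NEG)
            obs = s < NSTATES
            lp = logP[i]
            Li[obs] = lp[:, s[obs]].T
            Li[~obs] = 0.0
            L[i] = Li
            continue
        kids = tree.children[i]
        all_gap[i] = np.logical_and.reduce([all_gap[c] for c in kids])
        inner = np.zeros((ncols, NSTATES))  # best log-prob below i given own state x
        for c in kids:
            inner += L[c]
        if i == tree.root:
            M = inner + logpi[None, :]
            choice[i][:, 0] = M.argmax(axis=1)
            continue
        # M[col, p, x] = logP[p, x] + inner[col, x]
        M = logP[i][None, :, :] + inner[:, None, :]
        L[i] = M.max(axis=2)
        choice[i] = M.argmax(axis=2)  # first index on ties: A < C < G < T

    # traceback
    assigned = np.zeros((n, ncols), dtype=np.int8)
    out: dict[int, np.ndarray] = {}
    for i in reversed(tree.postorder):  # preorder
        if tree.is_leaf(i):
            continue
        if i == tree.root:
            assigned[i] = choice[i][:, 0]
        else:
            p = tree.parent[i]
            assigned[i] = np.take_along_axis(
                choice[i], assigned[p][:, None], axis=1
            )[:, 0]
        rec = assigned[i].copy()
        rec[all_gap[i]] = MISSING
        out[i] = rec
    return out


def ancestor_strings(
    ancestors: dict[int, np.ndarray], gap_char: str = "-"
) -> dict[int, str]:
    table = CODE_TO_BASE + gap_char
    return {
        node: "".join(table[c] for c in codes) for node, codes in ancestors.items()
    }
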