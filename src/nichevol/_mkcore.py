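"""Compiled inner loops for discrete-character pruning likelihoods.

These kernels operate on the flat array layout of :class:`nichevol.tree.PhyloTree`
(tips first, internal nodes in postorder, root last).  ``P`` holds one
transition-probability matrix per node for the edge *above* that node (the
root's entry is ignored).  Conditional likelihoods are max-rescaled per node;
the accumulated log scale is returned separately.
"""

import numpy as np
from numba import njit

__all__ = ["prune_partials", "prune_root"]


@njit(cache=True)
def prune_partials(P, tipstate, child_ptr, child_idx, n_tips):
    """Postorder conditional likelihoods for every node.

    Returns ``(L, logscale)`` with ``L[node]`` the rescaled partial
    likelihood vector and ``logscale`` the total log of the rescale factors.
    ``logscale`` is ``-inf`` when the data are impossible under ``P``.
    """
    n_nodes = P.shape[0]
    k = P.shape[1]
    L = np.zeros((n_nodes, k))
    for i in range(n_tips):
        L[i, tipstate[i]] = 1.0
    logscale = 0.0
    for j in range(n_nodes - n_tips):
        node = n_tips + j
        tmp = np.ones(k)
        for cpos in range(child_ptr[j], child_ptr[j + 1]):
            c = child_idx[cpos]
            for a in range(k):
                s = 0.0
                for b in range(k):
                    s += P[c, a, b] * L[c, b]
                tmp[a] *= s
        m = tmp[0]
        for a in range(1, k):
            if tmp[a] > m:
                m = tmp[a]
        if m <= 0.0:
            return L, -np.inf
        for a in range(k):
            L[node, a] = tmp[a] / m
        logscale += np.log(m)
    return L, logscale


@njit(cache=True)
def prune_root(P, tipstate, child_ptr, child_idx, n_tips):
    """Root partial likelihoods only: ``(L_root, logscale)``."""
    L, logscale = prune_partials(P, tipstate, child_ptr, child_idx, n_tips)
    return L[P.shape[0] - 1], logscale
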