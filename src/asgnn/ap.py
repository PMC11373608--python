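"""Affinity propagation clustering on a precomputed similarity matrix.

Exemplar-based clustering via damped responsibility/availability message
passing (Frey & Dueck).  Implemented here so that the non-convergence
behaviour is well-defined: if the exemplar set has not stabilized within the
iteration budget, the last iterate's assignment is returned and a warning is
logged, so every spot always receives a cluster.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["affinity_propagation"]


def affinity_propagation(
    similarity: np.ndarray,
    preference: float | np.ndarray | None = None,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Cluster points given pairwise similarities.

    Parameters
    ----------
    similarity
        (n, n) similarity matrix (larger = more similar); the diagonal is
        overwritten by ``preference``.
    preference
        Per-point preference for becoming an exemplar; scalar or length-n
        vector.  Defaults to the median of the off-diagonal similarities
        (the classical choice when no prior is available).
    damping
        Message damping factor in [0.5, 1).
    max_iter, convergence_iter
        Iteration budget and the number of iterations the exemplar set must
        stay unchanged to declare convergence.

    Returns
    -------
    labels : (n,) int
        0-based cluster labels.
    exemplars : (k,) int
        Point indices of the cluster exemplars, one per label.
    converged : bool
    """
    S = np.array(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be square")
    if not np.all(np.isfinite(S)):
        raise ValueError("similarity must be finite")
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must be in [0.5, 1)")
    n = S.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int), np.zeros(1, dtype=int), True

    if preference is None:
        off = S[~np.eye(n, dtype=bool)]
        preference = float(np.median(off))
    S[np.diag_indices_from(S)] = preference

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)

    stable = 0
    prev_exemplars: np.ndarray | None = None
    converged = False
    for _ in range(max_iter):
        # responsibilities
        AS = A + S
        first = AS.argmax(axis=1)
        first_val = AS[idx, first]
        AS[idx, first] = -np.inf
        second_val = AS.max(axis=1)
        Rnew = S - first_val[:, None]
        Rnew[idx, first] = S[idx, first] - second_val
        R = damping * R + (1 - damping) * Rnew

        # availabilities
        Rp = np.maximum(R, 0)
        Rp[np.diag_indices_from(Rp)] = R.diagonal()
        col = Rp.sum(axis=0)
        Anew = col[None, :] - Rp
        diag = Anew.diagonal().copy()
        Anew = np.minimum(Anew, 0)
        Anew[np.diag_indices_from(Anew)] = diag
        A = damping * A + (1 - damping) * Anew

        exemplars = np.flatnonzero(A.diagonal() + R.diagonal() > 0)
        if prev_exemplars is not None and np.array_equal(
            exemplars, prev_exemplars
        ):
            stable += 1
            if stable >= convergence_iter and exemplars.size > 0:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    if not converged:
        logger.warning(
            "affinity propagation did not converge in %d iterations; "
            "using the last iterate's exemplar assignment",
            max_iter,
        )
    exemplars = np.flatnonzero(A.diagonal() + R.diagonal() > 0)
    if exemplars.size == 0:
        # degenerate: fall back to the single best self-evidence point
        exemplars = np.array([int((A.diagonal() + R.diagonal()).argmax())])
    # assign, then refine each exemplar to the point maximizing the summed
    # within-cluster similarity (the reference implementation's final step)
    c = S[:, exemplars].argmax(axis=1)
    c[exemplars] = np.arange(exemplars.size)
    for k in range(exemplars.size):
        members = np.flatnonzero(c == k)
        best = members[S[np.ix_(members, members)].sum(axis=0).argmax()]
        exemplars[k] = best
    exemplars = np.sort(exemplars)
    c = S[:, exemplars].argmax(axis=1)
    c[exemplars] = np.arange(exemplars.size)
    return c.astype(int), exemplars.astype(int), converged
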