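"""Numba kernels for gene-dropping Monte Carlo over a pedigree.

Founder allele copies receive globally unique labels; labels are dropped
through the pedigree by simulated meiosis (tetrasomic with double reduction
``w``, or disomic) and pairwise identity-by-descent is scored as the
fraction of cross allele pairs sharing a label. A missing parent acts as a
fresh, unrelated, non-inbred founder whose gametes still undergo double
reduction.

The kernels accumulate per-replicate match counts and their squares so the
caller can form ploidy-scaled coancestry estimates together with Monte-Carlo
standard errors.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _drop_tetra(par, w, n_rep, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n = par.shape[0]
    lab = np.empty((n, 4), np.int64)
    s_m = np.zeros((n, n), np.float64)
    s_m2 = np.zeros((n, n), np.float64)
    for _ in range(n_rep):
        nxt = 0
        for i in range(n):
            s = par[i, 0]
            d = par[i, 1]
            if s < 0 and d < 0:
                for c in range(4):
                    lab[i, c] = nxt
                    nxt += 1
            else:
                for g in range(2):
                    parent = s if g == 0 else d
                    off = 2 * g
                    if parent < 0:
                        # phantom founder gamete
                        if np.random.random() < w:
                            lab[i, off] = nxt
                            lab[i, off + 1] = nxt
                            nxt += 1
                        else:
                            lab[i, off] = nxt
                            lab[i, off + 1] = nxt + 1
                            nxt += 2
                    elif np.random.random() < w:
                        a = lab[parent, np.random.randint(4)]
                        lab[i, off] = a
                        lab[i, off + 1] = a
                    else:
                        c1 = np.random.randint(4)
                        c2 = np.random.randint(3)
                        if c2 >= c1:
                            c2 += 1
                        lab[i, off] = lab[parent, c1]
                        lab[i, off + 1] = lab[parent, c2]
        for i in range(n):
            for j in range(i, n):
                m = 0
                for a in range(4):
                    for b in range(4):
                        if lab[i, a] == lab[j, b]:
                            m += 1
                s_m[i, j] += m
                s_m2[i, j] += m * m
    return s_m, s_m2


@njit(cache=True)
def _drop_di(par, n_rep, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n = par.shape[0]
    lab = np.empty((n, 2), np.int64)
    s_m = np.zeros((n, n), np.float64)
    s_m2 = np.zeros((n, n), np.float64)
    for _ in range(n_rep):
        nxt = 0
        for i in range(n):
            s = par[i, 0]
            d = par[i, 1]
            for g in range(2):
                parent = s if g == 0 else d
                if parent < 0:
                    lab[i, g] = nxt
                    nxt += 1
                else:
                    lab[i, g] = lab[parent, np.random.randint(2)]
        for i in range(n):
            for j in range(i, n):
                m = 0
                for a in range(2):
                    for b in range(2):
                        if lab[i, a] == lab[j, b]:
                            m += 1
                s_m[i, j] += m
                s_m2[i, j] += m * m
    return s_m, s_m2
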