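"""Independent oracles used by the test suite.

Gene dropping: simulate Mendelian transmission of distinct founder
alleles down the pedigree many times; the expected fraction of matching
allele draws between two individuals estimates their coancestry, hence
the additive relationship a_ij = 2 f_ij, independently of the tabular
recursion being tested.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gene_drop_relationship(sire, dam, reps, seed):
    np.random.seed(seed)
    n = sire.shape[0]
    counts = np.zeros((n, n))
    a1 = np.empty(n, np.int64)
    a2 = np.empty(n, np.int64)
    for _ in range(reps):
        nall = 0
        for i in range(n):
            s = sire[i]
            if s < 0:
                a1[i] = nall
                nall += 1
            else:
                a1[i] = a1[s] if np.random.random() < 0.5 else a2[s]
            d = dam[i]
            if d < 0:
                a2[i] = nall
                nall += 1
            else:
                a2[i] = a1[d] if np.random.random() < 0.5 else a2[d]
        for i in range(n):
            for j in range(i, n):
                c = 0
                if a1[i] == a1[j]:
                    c += 1
                if a1[i] == a2[j]:
                    c += 1
                if a2[i] == a1[j]:
                    c += 1
                if a2[i] == a2[j]:
                    c += 1
                counts[i, j] += c
    A = counts / (2.0 * reps)
    for i in range(n):
        for j in range(i + 1, n):
            A[j, i] = A[i, j]
    return A


def midparent_regression_h2(ped, pheno, trait):
    """Offspring-midparent regression: slope estimates h^2."""
    idx = {iid: i for i, iid in enumerate(pheno["individual_id"])}
    y = pheno[trait].to_numpy()
    xs, ys = [], []
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 or d < 0:
            continue
        ids = ped.ids
        if ids[i] in idx and ids[s] in idx and ids[d] in idx:
            o, ps, pd_ = y[idx[ids[i]]], y[idx[ids[s]]], y[idx[ids[d]]]
            if np.isfinite(o) and np.isfinite(ps) and np.isfinite(pd_):
                xs.append(0.5 * (ps + pd_))
                ys.append(o)
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    b = np.cov(xs, ys)[0, 1] / np.var(xs)
    return b
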