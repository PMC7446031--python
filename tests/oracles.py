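"""Independent brute-force oracles for the rank statistics and the
sign-flip cluster test (plain loops and exhaustive enumeration only)."""

import itertools

import numpy as np
from scipy import stats


def tau_a_oracle(x, y):
    """Exhaustive pair enumeration: (C - D) / (n(n-1)/2)."""
    n = len(x)
    c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[j] - x[i]) * (y[j] - y[i])
            if s > 0:
                c += 1
            elif s < 0:
                d += 1
    return (c - d) / (n * (n - 1) / 2)


def wilcoxon_oracle(values, alternative="greater"):
    """Brute-force enumeration of all 2^n sign assignments of the midranks."""
    values = np.asarray(values, dtype=float)
    nz = values[values != 0]
    ranks = stats.rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    ws = [np.sum([r for r, s in zip(ranks, signs) if s])
          for signs in itertools.product([False, True], repeat=len(nz))]
    ws = np.array(ws)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    p_le = np.mean(ws <= w_obs + 1e-9)
    if alternative == "greater":
        return w_obs, p_ge
    return w_obs, min(1.0, 2 * min(p_ge, p_le))


def cluster_oracle_exhaustive(X, alpha=0.05):
    """Cluster p by full enumeration of all 2^n participant sign flips,
    written independently of the implementation (plain loops)."""
    n, T = X.shape

    def pointwise(Y):
        out = []
        for t in range(T):
            col = Y[:, t][Y[:, t] != 0]
            ranks = stats.rankdata(np.abs(col))
            w = ranks[col > 0].sum()
            null = [np.sum([r for r, s in zip(ranks, sg) if s])
                    for sg in itertools.product([False, True], repeat=len(col))]
            p = np.mean(np.asarray(null) >= w - 1e-9)
            mu = ranks.sum() / 2
            sd = np.sqrt((ranks**2).sum()) / 2
            out.append((p <= alpha, (w - mu) / sd if sd > 0 else 0.0))
        return out

    def max_mass(Y):
        best = 0.0
        cur = 0.0
        for sig, z in pointwise(Y):
            if sig:
                cur += z
                best = max(best, cur)
            else:
                cur = 0.0
        return best

    def clusters(Y):
        out = []
        cur = None
        for t, (sig, z) in enumerate(pointwise(Y)):
            if sig:
                if cur is None:
                    cur = [t, t, z]
                else:
                    cur[1] = t
                    cur[2] += z
            elif cur is not None:
                out.append(tuple(cur))
                cur = None
        if cur is not None:
            out.append(tuple(cur))
        return out

    null = np.array([max_mass(np.array(sg)[:, None] * X)
                     for sg in itertools.product([-1.0, 1.0], repeat=n)])
    return [(a, b, mass, np.mean(null >= mass - 1e-12))
            for a, b, mass in clusters(X)]


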