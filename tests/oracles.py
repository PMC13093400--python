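"""Independent brute-force oracles used to verify the implementations.

Each oracle takes a different computational route than the code it checks:
path counting instead of the tabular recursion, exhaustive enumeration
instead of dynamic programming, direct factorial formulas instead of
recurrences.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- Wright path-counting inbreeding -----------------------------------------


def wright_fped(parents: dict[str, tuple[str | None, str | None]], ind: str) -> float:
    """F of ``ind`` as a sum over common-ancestor path pairs.

    F = sum over common ancestors A and over pairs of ancestral paths
    (sire -> A, dam -> A) sharing no intermediate node, of
    (1/2)^(L1 + L2 + 1) * (1 + F_A).
    """
    s, d = parents[ind]
    if s is None or d is None:
        return 0.0
    return _wright_kinship_paths(parents, s, d)


def _ancestor_paths(parents, start):
    """All upward paths start -> ancestor as node tuples (start included)."""
    out = [(start,)]
    s, d = parents.get(start, (None, None))
    for p in (s, d):
        if p is not None:
            out.extend((start,) + path for path in _ancestor_paths(parents, p))
    return out

def _wright_kinship_paths(parents, i, j) -> float:
    total = 0.0
    paths_i = _ancestor_paths(parents, i)
    paths_j = _ancestor_paths(parents, j)
    for pi in paths_i:
        for pj in paths_j:
            if pi[-1] != pj[-1]:
                continue
            a = pi[-1]
            # paths must be node-disjoint except for the common ancestor
            if set(pi[:-1]) & set(pj[:-1]):
                continue
            l1, l2 = len(pi) - 1, len(pj) - 1
            fa = wright_fped(parents, a)
            total += 0.5 ** (l1 + l2 + 1) * (1 + fa)
    return total


# --- exhaustive HMM decoding -------------------------------------------------


def viterbi_bruteforce(log_emis: np.ndarray, log_trans: np.ndarray, log_pi: np.ndarray):
    """Best state path by enumerating all 2^n paths.

    log_emis: (n, 2); log_trans: (n-1, 2, 2); returns (best logprob, path).
    """
    n = log_emis.shape[0]
    best, best_path = -np.inf, None
    for path in itertools.product((0, 1), repeat=n):
        lp = log_pi[path[0]] + log_emis[0, path[0]]
        for t in range(1, n):
            lp += log_trans[t - 1, path[t - 1], path[t]] + log_emis[t, path[t]]
        if lp > best:
            best, best_path = lp, path
    return best, np.array(best_path)


def posterior_bruteforce(log_emis: np.ndarray, log_trans: np.ndarray, log_pi: np.ndarray):
    """P(state_t = s | data) by summing over all paths; returns (n, 2)."""
    n = log_emis.shape[0]
    tot = np.zeros((n, 2))
    z = 0.0
    for path in itertools.product((0, 1), repeat=n):
        lp = log_pi[path[0]] + log_emis[0, path[0]]
        for t in range(1, n):
            lp += log_trans[t - 1, path[t - 1], path[t]] + log_emis[t, path[t]]
        w = math.exp(lp)
        z += w
        for t in range(n):
            tot[t, path[t]] += w
    return tot / z


# --- exact Hardy-Weinberg test via direct formula ----------------------------


def hwe_exact_enum(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p by the closed-form conditional probability of each
    heterozygote count (Levene/Haldane formula), summed over outcomes no
    more probable than the observed one."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    rare = min(na, nb)
    if rare == 0:
        return 1.0

    def prob(h):
        hom_r = (rare - h) // 2
        hom_c = n - hom_r - h
        return (
            math.comb(n, hom_r)
            * math.comb(n - hom_r, hom_c)
            * math.comb(n - hom_r - hom_c, h)
            * 2**h
            / math.comb(2 * n, rare)
        )

    hets = range(rare % 2, rare + 1, 2)
    ps = {h: prob(h) for h in hets}
    p_obs = ps[n_ab]
    return min(1.0, sum(p for p in ps.values() if p <= p_obs * (1 + 1e-12)))


# --- signed-rank and Kendall oracles -----------------------------------------


def wilcoxon_enum(d: np.ndarray):
    """(V, exact two-sided p) by enumerating all sign assignments.

    Zeros dropped; mid-ranks for tied absolute values; p is the probability
    under the null (signs independent, fair) of a V at least as extreme in
    either tail.
    """
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    r = rankdata(np.abs(d))
    v_obs = r[d > 0].sum()
    vs = [r[list(signs)].sum() for signs in _subsets(n)]
    vs = np.array(vs)
    mean_v = r.sum() / 2
    dev = abs(v_obs - mean_v)
    p = np.mean(np.abs(vs - mean_v) >= dev - 1e-12)
    return float(v_obs), float(p)


def _subsets(n):
    for mask in range(2**n):
        yield [i for i in range(n) if mask >> i & 1]


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Direct O(n^2) tau-b with tie corrections."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                tx += 1
                ty += 1
            elif a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom


# --- Welch's t by hand -------------------------------------------------------


def welch_t_hand(a: np.ndarray, b: np.ndarray):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


# --- random pedigree generator for oracle comparisons ------------------------


def random_pedigree(rng: np.random.Generator, n: int):
    """Random acyclic pedigree as {id: (sire|None, dam|None)}; individuals
    labelled by index, parents always have lower index."""
    parents: dict[str, tuple[str | None, str | None]] = {}
    for i in range(n):
        if i < 2 or rng.random() < 0.3:
            parents[str(i)] = (None, None)
            continue
        s = str(int(rng.integers(0, i)))
        d = str(int(rng.integers(0, i)))
        if s == d:
            parents[str(i)] = (s, None)
        else:
            parents[str(i)] = (s, d)
    return parents
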