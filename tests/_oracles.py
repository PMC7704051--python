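"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (explicit sorts, O(N^2) scans,
dense unscaled DP in extended precision) and shares no code with the
package's optimized implementations.
"""

import numpy as np


def reverse_prefix_order(H: np.ndarray, m: int) -> np.ndarray:
    """Stable lexicographic sort of haplotypes by reversed prefix
    ``h[m..0]`` (ties keep original order)."""
    keys = [tuple(H[n, : m + 1][::-1]) for n in range(H.shape[0])]
    return np.array(sorted(range(H.shape[0]), key=lambda n: keys[n]))


def match_start(H: np.ndarray, a: int, b: int, m: int) -> int:
    """Start of the maximal common reverse prefix of haplotypes a and b
    ending at marker m, by direct backward scan."""
    s = m + 1
    for j in range(m, -1, -1):
        if H[a, j] != H[b, j]:
            break
        s = j
    return s


def insertion_slot(H: np.ndarray, target: np.ndarray, m: int) -> int:
    """Number of reference reverse prefixes lexicographically smaller
    than the target's reverse prefix at marker m."""
    tkey = tuple(target[: m + 1][::-1])
    return sum(
        1 for n in range(H.shape[0]) if tuple(H[n, : m + 1][::-1]) < tkey
    )


def longest_match_haplotype(H: np.ndarray, target: np.ndarray, m: int) -> set:
    """Reference haplotypes achieving the maximal reverse-prefix match
    length with the target at marker m (a set; ties are common)."""
    n = H.shape[0]
    starts = [
        match_start(np.vstack([H, target[None, :]]), a, n, m) for a in range(n)
    ]
    best = min(starts)
    return {a for a in range(n) if starts[a] == best}


def dense_forward_backward(
    target: np.ndarray,
    state_alleles: np.ndarray,
    cm: np.ndarray,
    ne: float = 20000.0,
    e_match: float = 0.9999,
    min_rho: float = 1e-9,
) -> np.ndarray:
    """O(S^2 T) forward-backward with explicit transition matrices, in
    extended precision with no per-marker rescaling."""
    S, T = state_alleles.shape
    em = np.where(
        state_alleles.T == target[:, None], e_match, 1.0 - e_match
    ).astype(np.longdouble)
    al = np.zeros((T, S), dtype=np.longdouble)
    al[0] = em[0] / S
    trans = []
    for m in range(T - 1):
        r = max(min_rho, 1.0 - np.exp(-4.0 * ne * ((cm[m + 1] - cm[m]) / 100.0) / S))
        trans.append(np.full((S, S), r / S, dtype=np.longdouble) + np.eye(S) * (1.0 - r))
    for m in range(1, T):
        al[m] = em[m] * (al[m - 1] @ trans[m - 1])
    be = np.zeros((T, S), dtype=np.longdouble)
    be[-1] = 1.0
    for m in range(T - 2, -1, -1):
        be[m] = trans[m] @ (em[m + 1] * be[m + 1])
    post = al * be
    return (post / post.sum(axis=1, keepdims=True)).astype(float)


def dense_impute(
    target: np.ndarray,
    ref_all: np.ndarray,
    typed_idx: np.ndarray,
    cm: np.ndarray,
    ne: float = 20000.0,
) -> np.ndarray:
    """Full-panel Li & Stephens imputation of every marker: dense
    forward-backward at typed markers over *all* reference haplotypes,
    then linear cM interpolation of the per-state posteriors.

    Returns haploid alt probabilities at all markers of ``ref_all``.
    """
    typed_idx = np.asarray(typed_idx)
    H_t = ref_all[:, typed_idx]
    post = dense_forward_backward(target, H_t, cm[typed_idx], ne=ne)
    n_all = ref_all.shape[1]
    out = np.empty(n_all)
    t_cm = cm[typed_idx]
    typed_set = {int(i): j for j, i in enumerate(typed_idx)}
    for u in range(n_all):
        if u in typed_set:
            p = post[typed_set[u]]
        else:
            j = int(np.searchsorted(typed_idx, u))
            if j == 0:
                p = post[0]
            elif j == len(typed_idx):
                p = post[-1]
            else:
                span = t_cm[j] - t_cm[j - 1]
                w = 0.0 if span <= 0 else (cm[u] - t_cm[j - 1]) / span
                w = min(max(w, 0.0), 1.0)
                p = (1.0 - w) * post[j - 1] + w * post[j]
        out[u] = float(p @ ref_all[:, u])
    return np.clip(out, 0.0, 1.0)
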