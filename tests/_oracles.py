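"""Independent brute-force re-implementations used as test oracles.

Everything here is written with plain Python loops and ``sorted`` so that it
shares no code path with the package implementation.
"""

import numpy as np


def closeness_rank_map(values, self_index=None):
    """{reference index: closeness rank}, 1 = most proximal, ties broken by
    ascending index; ``self_index`` forced to rank 1."""
    order = sorted(range(len(values)),
                   key=lambda j: (j != self_index, -values[j], j))
    return {j: r + 1 for r, j in enumerate(order)}


def brute_rs(clin_prox, mol_prox, clin_ok, mol_ok, k, g_variant="difference"):
    """Right, Wrong and RS for every test row, straight from the definitions."""
    clin_prox = np.atleast_2d(clin_prox)
    n = len(clin_ok)

    g_r, g_w = [], []
    for l in range(n):
        ranks = closeness_rank_map(mol_prox[l], self_index=l)
        correct = sorted([j for j in range(n) if mol_ok[j]], key=lambda j: ranks[j])
        wrong = sorted([j for j in range(n) if not mol_ok[j]], key=lambda j: ranks[j])
        g_r.append(sum(ranks[j] / (t + 1) for t, j in enumerate(correct[:k])))
        g_w.append(sum(ranks[j] / (t + 1) for t, j in enumerate(wrong[:k])))
    if g_variant == "difference":
        g_right = g_wrong = [w - r for r, w in zip(g_r, g_w)]
    else:
        g_right, g_wrong = g_r, g_w

    rights, wrongs, scores = [], [], []
    for row in clin_prox:
        ranks = closeness_rank_map(row)
        correct = sorted([j for j in range(n) if clin_ok[j]], key=lambda j: ranks[j])
        wrong = sorted([j for j in range(n) if not clin_ok[j]], key=lambda j: ranks[j])
        right = sum(ranks[l] / (j + 1) * g_right[l] for j, l in enumerate(correct[:k]))
        wr = sum(ranks[l] / (j + 1) * g_wrong[l] for j, l in enumerate(wrong[:k]))
        rights.append(right)
        wrongs.append(wr)
        scores.append(right - wr)
    return np.array(rights), np.array(wrongs), np.array(scores)


def random_rs_instance(rng, max_n=20, max_k=3, n_test=None):
    """A random proximity/flag configuration with a feasible K."""
    n = int(rng.integers(4, max_n + 1))
    m = n_test if n_test is not None else int(rng.integers(1, 5))
    clin_prox = np.round(rng.random((m, n)), 2)  # rounding forces ties
    mol = np.round(rng.random((n, n)), 2)
    mol_prox = (mol + mol.T) / 2.0
    np.fill_diagonal(mol_prox, 1.0)
    while True:
        clin_ok = rng.random(n) < rng.uniform(0.2, 0.8)
        mol_ok = rng.random(n) < rng.uniform(0.2, 0.8)
        counts = [clin_ok.sum(), (~clin_ok).sum(), mol_ok.sum(), (~mol_ok).sum()]
        if min(counts) > 0:
            break
    k = int(min(min(counts), rng.integers(1, max_k + 1)))
    return clin_prox, mol_prox, clin_ok, mol_ok, k
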