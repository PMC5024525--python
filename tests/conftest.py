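"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from censatkit.ancestral_reconstruction import Phylogeny


@pytest.fixture
def rng():
    return np.random.default_rng(20160915)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately simple / brute force)
# ---------------------------------------------------------------------------


def slow_wraparound_score(seq: str, consensus: str, mw=1, mm=1, gw=2) -> int:
    """Reference wraparound local alignment score by naive relaxation.

    Plain dictionary DP over (row, column) cells; within-row wraparound gap
    moves are relaxed by sweeping each row repeatedly until a fixed point —
    no vectorization, no prefix-scan shortcut.
    """
    n, p = len(seq), len(consensus)
    prev = [0] * p
    best = 0
    for i in range(1, n + 1):
        ch = seq[i - 1]
        cur = []
        for j in range(p):
            sub = mw if consensus[j] == ch else -mm
            val = max(prev[(j - 1) % p] + sub, prev[j] - gw, 0)
            cur.append(val)
        changed = True
        while changed:
            changed = False
            for j in range(p):
                cand = cur[(j - 1) % p] - gw
                if cand > cur[j]:
                    cur[j] = cand
                    changed = True
        best = max(best, max(cur))
        prev = cur
    return best


def exhaustive_linear_cost(tree: Phylogeny, tip_values: dict[str, float]) -> float:
    """Minimum sum(|parent-child|) by enumerating internal states.

    For linear (Manhattan) parsimony an optimal labeling exists with every
    internal state drawn from the set of tip values, so enumeration over
    that set is exact. Only feasible for small trees.
    """
    internal = [i for i in range(tree.n_nodes) if not tree.is_tip(i)]
    candidates = sorted(set(tip_values.values()))
    fixed = {
        i: tip_values[tree.labels[i]]
        for i in range(tree.n_nodes)
        if tree.is_tip(i)
    }
    edges = [
        (tree.parent[i], i) for i in range(tree.n_nodes) if tree.parent[i] is not None
    ]
    best = float("inf")
    for combo in itertools.product(candidates, repeat=len(internal)):
        states = dict(fixed)
        states.update(dict(zip(internal, combo)))
        cost = sum(abs(states[a] - states[b]) for a, b in edges)
        best = min(best, cost)
    return best


def dense_squared_change_solve(
    tree: Phylogeny, tip_values: dict[str, float], weighted: bool = False
) -> dict[str, float]:
    """Squared-change optimum by assembling and solving the normal equations."""
    n = tree.n_nodes
    if weighted:
        w = [0.0 if i == tree.root else 1.0 / tree.edge_length[i] for i in range(n)]
    else:
        w = [1.0] * n
    internal = [i for i in range(n) if not tree.is_tip(i)]
    index = {node: k for k, node in enumerate(internal)}
    A = np.zeros((len(internal), len(internal)))
    b = np.zeros(len(internal))
    for i in internal:
        neigh = ([(tree.parent[i], w[i])] if tree.parent[i] is not None else []) + [
            (c, w[c]) for c in tree.children[i]
        ]
        for v, wt in neigh:
            A[index[i], index[i]] += wt
            if v in index:
                A[index[i], index[v]] -= wt
            else:
                b[index[i]] += wt * tip_values[tree.labels[v]]
    x = np.linalg.solve(A, b)
    states = {tree.labels[i]: tip_values[tree.labels[i]] for i in range(n) if tree.is_tip(i)}
    states.update({tree.labels[i]: float(x[index[i]]) for i in internal})
    return states


def random_binary_tree(
    n_tips: int, rng: np.random.Generator, branch_scale: float = 1.0
) -> Phylogeny:
    """Random rooted binary topology by successive joining, branch lengths ~U(0.5, 1.5)."""
    subtrees = [f"T{i}:{branch_scale * rng.uniform(0.5, 1.5):.4f}" for i in range(n_tips)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        length = branch_scale * rng.uniform(0.5, 1.5)
        subtrees.append(f"({left},{right}):{length:.4f}")
    newick = subtrees[0].rsplit(":", 1)[0] + ";"
    return Phylogeny.from_newick(newick)


def union_find_components(n_nodes: int, edges) -> list[frozenset[int]]:
    """Connected components by a plain union-find, as a clustering oracle."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, set[int]] = {}
    for i in range(n_nodes):
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)
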