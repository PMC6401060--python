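"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's pruning/eigendecomposition
machinery: rate matrices are assembled by direct loops, branch transition
matrices use ``scipy.linalg.expm`` on explicitly split segments, and tree
likelihoods/posteriors are obtained by exhaustive enumeration over joint
assignments of range states to internal nodes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import scipy.linalg

from stratodec.geography import Geography, DispersalModelSpec
from stratodec.phylo import Phylogeny
from stratodec.simulate import simulate_yule_tree


# ----------------------------------------------------------------------
# Independent oracle machinery
# ----------------------------------------------------------------------

def oracle_states(n_areas: int) -> list[int]:
    """Null plus all non-null masks, ordered by (popcount, mask)."""
    masks = sorted(range(1, 1 << n_areas), key=lambda m: (bin(m).count("1"), m))
    return [0] + masks


def oracle_clado(parent: int) -> list[tuple[tuple[int, int], float]]:
    """DEC cladogenesis scenarios by direct set construction."""
    bits = [i for i in range(parent.bit_length()) if parent >> i & 1]
    if len(bits) == 1:
        return [((parent, parent), 1.0)]
    pairs = set()
    for i in bits:
        s = 1 << i
        rest = parent & ~s
        pairs |= {(s, rest), (rest, s), (s, parent), (parent, s)}
    pairs = sorted(pairs)
    return [(p, 1.0 / len(pairs)) for p in pairs]


def oracle_rate_matrix(d: float, e: float, mult: np.ndarray, masks: list[int]) -> np.ndarray:
    n_areas = mult.shape[0]
    K = len(masks)
    idx = {m: i for i, m in enumerate(masks)}
    Q = np.zeros((K, K))
    for a, mask in enumerate(masks):
        if mask == 0:
            continue
        for k in range(n_areas):
            if mask >> k & 1:
                dst = mask & ~(1 << k)
                if dst in idx:
                    Q[a, idx[dst]] += e
            else:
                rate = d * sum(mult[i, k] for i in range(n_areas) if mask >> i & 1)
                dst = mask | (1 << k)
                if dst in idx and rate > 0:
                    Q[a, idx[dst]] += rate
        Q[a, a] = -Q[a].sum()
    return Q


def oracle_branch_matrix(child_age, parent_age, slices, Qs) -> np.ndarray:
    """Old-to-young product of segment exponentials via scipy expm."""
    P = np.eye(Qs[0].shape[0])
    for s in range(len(slices) - 1, -1, -1):
        lo = max(child_age, slices[s].young_bound)
        hi = min(parent_age, slices[s].old_bound)
        if hi > lo + 1e-12:
            P = P @ scipy.linalg.expm(Qs[s] * (hi - lo))
    return P


def oracle_joint_terms(tree: Phylogeny, tips: dict, d, e, geography: Geography,
                       spec: DispersalModelSpec):
    """Joint probability of the tip data and each internal-node state assignment.

    Yields ``(assignment, probability)`` over all assignments of non-null
    range states to internal nodes, summing scenario choices per node.
    """
    masks = oracle_states(geography.n_areas)
    nonnull = masks[1:]
    idx = {m: i for i, m in enumerate(masks)}
    slices, mults = geography.multiplier_matrices(max(tree.root_age, 1e-12), spec)
    Qs = [oracle_rate_matrix(d, e, m, masks) for m in mults]
    P = {}
    for v in range(tree.n_nodes):
        if tree.parent[v] >= 0:
            P[v] = oracle_branch_matrix(
                tree.age[v], tree.age[tree.parent[v]], slices, Qs
            )
    internals = tree.internal_nodes()
    prior = 1.0 / len(nonnull)

    def end_index(v, assign):
        if tree.is_tip(v):
            return idx[tips[tree.tip_labels[v]]]
        return idx[assign[v]]

    for combo in itertools.product(nonnull, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        prob = prior
        for v in internals:
            c1, c2 = tree.children[v]
            node_sum = 0.0
            for (l, r), p in oracle_clado(assign[v]):
                node_sum += (
                    p
                    * P[c1][idx[l], end_index(c1, assign)]
                    * P[c2][idx[r], end_index(c2, assign)]
                )
            prob *= node_sum
        yield assign, prob


def oracle_loglike(tree, tips, d, e, geography, spec) -> float:
    total = sum(p for _, p in oracle_joint_terms(tree, tips, d, e, geography, spec))
    return np.log(total)


def oracle_marginals(tree, tips, d, e, geography, spec):
    """Posterior P(node state | data) by exhaustive enumeration."""
    masks = oracle_states(geography.n_areas)
    internals = tree.internal_nodes()
    acc = {v: np.zeros(len(masks)) for v in internals}
    idx = {m: i for i, m in enumerate(masks)}
    total = 0.0
    for assign, p in oracle_joint_terms(tree, tips, d, e, geography, spec):
        total += p
        for v in internals:
            acc[v][idx[assign[v]]] += p
    return {v: acc[v] / total for v in internals}


def oracle_sankoff_cost(tree: Phylogeny, tips: dict, n_areas: int) -> float:
    """Exhaustive minimum symmetric-difference cost over internal assignments."""
    nonnull = oracle_states(n_areas)[1:]
    internals = tree.internal_nodes()

    def state_of(v, assign):
        return tips[tree.tip_labels[v]] if tree.is_tip(v) else assign[v]

    best = np.inf
    for combo in itertools.product(nonnull, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        cost = 0
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p >= 0:
                cost += bin(state_of(v, assign) ^ state_of(p, assign)).count("1")
        best = min(best, cost)
    return best


def chisquare_lumped(counts: np.ndarray, probs: np.ndarray) -> float:
    """Goodness-of-fit p-value, lumping bins with expected count < 5."""
    import scipy.stats

    n = counts.sum()
    expected = probs * n
    keep = expected >= 5
    obs = list(counts[keep])
    exp = list(expected[keep])
    if (~keep).any() and expected[~keep].sum() > 0:
        obs.append(counts[~keep].sum())
        exp.append(expected[~keep].sum())
    obs, exp = np.array(obs, float), np.array(exp, float)
    exp *= obs.sum() / exp.sum()  # guard tiny truncation of the tail mass
    return scipy.stats.chisquare(obs, exp).pvalue


# ----------------------------------------------------------------------
# Random instance helpers
# ----------------------------------------------------------------------

def random_geography(rng: np.random.Generator, n_areas: int,
                     n_slices: int = 2, root_age: float = 10.0) -> Geography:
    """Random multi-slice geography with random multipliers, all areas available."""
    from stratodec.geography import Area, PaleoEvent

    areas = [Area(f"A{i}", i) for i in range(n_areas)]
    cuts = sorted(rng.uniform(0.5, root_age - 0.5, size=n_slices - 1))
    events = [PaleoEvent(f"ev{j}", float(c)) for j, c in enumerate(cuts)]
    dist = np.zeros((n_areas, n_areas), dtype=int)
    for i in range(n_areas):
        for j in range(i + 1, n_areas):
            dist[i, j] = dist[j, i] = rng.integers(0, 3)
    tiers = {0: 1.0, 1: float(rng.uniform(0.3, 0.8)), 2: float(rng.uniform(0.05, 0.3))}
    return Geography(areas=areas, events=events, distance_classes=dist, tiers=tiers)


def random_tree(rng: np.random.Generator, n_tips: int, root_age: float = 10.0) -> Phylogeny:
    return simulate_yule_tree(n_tips, 0.3, root_age, seed=int(rng.integers(2**31)))


def random_tips(rng: np.random.Generator, tree: Phylogeny, n_areas: int) -> dict:
    return {
        lab: int(rng.integers(1, 1 << n_areas)) for lab in tree.tip_labels
    }


@pytest.fixture(scope="session")
def study_fixture():
    from stratodec.simulate import make_study_fixture

    return make_study_fixture(seed=2020)


@pytest.fixture(scope="session")
def five_area():
    from stratodec.geography import caribbean_five_area

    return caribbean_five_area()
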