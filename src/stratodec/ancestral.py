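"""Ancestral range reconstruction: marginal DEC probabilities and Sankoff parsimony.

Two criteria are offered.  The probabilistic criterion computes, for every
internal node, the marginal posterior probability of each range state given
all tip data under the fitted DEC model (empirical Bayes: rates fixed at
their maximum-likelihood estimates), via a standard inside/outside pass
that respects the cladogenesis scenarios.  The parsimony criterion is
Sankoff's dynamic programme with a configurable symmetric step-cost matrix
(default: size of the symmetric difference between the two area sets),
returning the full set of most-parsimonious states per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import DECEngine, DECParameters
from .phylo import Phylogeny
from .states import enumerate_ranges, mask_to_labels, popcount

__all__ = [
    "AncestralReconstruction",
    "NodeSummary",
    "marginal_ancestral_ranges",
    "sankoff_parsimony",
    "summarize_node",
    "symmetric_difference_cost",
]


@dataclass
class NodeSummary:
    """Resolved/unresolved call for one internal node."""

    node: int
    labels: list[str]
    resolved: bool
    top_mass: float
    clade: frozenset[str]


@dataclass
class AncestralReconstruction:
    """Per-internal-node ancestral ranges under one criterion.

    ``method`` is ``"marginal"`` or ``"parsimony"``.  In marginal mode
    ``probabilities[v]`` is a vector over ``masks`` summing to one (null
    state carries zero mass).  In parsimony mode ``mpr_sets[v]`` is the
    non-empty set of range masks attaining the minimum total cost, which is
    stored in ``total_cost``.
    """

    method: str
    tree: Phylogeny
    masks: list[int]
    area_labels: list[str]
    probabilities: dict[int, np.ndarray] = field(default_factory=dict)
    mpr_sets: dict[int, set[int]] = field(default_factory=dict)
    total_cost: float | None = None
    params: DECParameters | None = None

    def nodes(self) -> list[int]:
        return self.tree.internal_nodes()

    def range_label(self, mask: int) -> str:
        return mask_to_labels(mask, self.area_labels)

    def summarize(self, node: int, threshold: float = 0.5) -> NodeSummary:
        return summarize_node(self, node, threshold)

    def node_table(self, threshold: float = 0.5, top_k: int = 3) -> pd.DataFrame:
        """One row per internal node: top ranges with their support."""
        rows = []
        for v in self.nodes():
            s = self.summarize(v, threshold)
            if self.method == "marginal":
                p = self.probabilities[v]
                order = np.argsort(p)[::-1][:top_k]
                tops = "; ".join(
                    f"{self.range_label(self.masks[i])}={p[i]:.3f}"
                    for i in order
                    if p[i] > 1e-12
                )
            else:
                tops = "; ".join(
                    sorted(self.range_label(m) for m in self.mpr_sets[v])
                )
            rows.append(
                {
                    "node": v,
                    "clade": "|".join(sorted(self.tree.clade_tips(v))),
                    "method": self.method,
                    "top_ranges": tops,
                    "best": "+".join(s.labels) if len(s.labels) == 1 else
                            " / ".join(s.labels),
                    "resolved": s.resolved,
                    "support": s.top_mass,
                }
            )
        return pd.DataFrame(rows)

    def pie_data(self, min_mass: float = 1e-6) -> dict[int, dict[str, float]]:
        """Range-label -> probability mass per node, for pie-chart plotting."""
        if self.method != "marginal":
            raise ValueError("pie data requires a marginal reconstruction")
        out = {}
        for v, p in self.probabilities.items():
            out[v] = {
                self.range_label(self.masks[i]): float(p[i])
                for i in range(len(p))
                if p[i] >= min_mass
            }
        return out

    def plot_pies(self, ax=None, max_slices: int = 6):  # pragma: no cover - visual
        """Bar-of-pies overview of node support (requires matplotlib)."""
        import matplotlib.pyplot as plt

        pies = self.pie_data()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * len(pies) + 1))
        for row, (v, masses) in enumerate(sorted(pies.items())):
            left = 0.0
            for lab, mass in sorted(masses.items(), key=lambda kv: -kv[1])[:max_slices]:
                ax.barh(row, mass, left=left, label=lab)
                left += mass
        ax.set_yticks(range(len(pies)))
        ax.set_yticklabels([f"node {v}" for v in sorted(pies)])
        ax.set_xlabel("posterior mass")
        return ax


def marginal_ancestral_ranges(fit, force: bool = False) -> AncestralReconstruction:
    """Marginal range probabilities at every internal node of a fitted model.

    ``fit`` is a :class:`~stratodec.model.DECResults`.  Refuses a
    non-converged fit unless ``force=True``.  The null (globally extinct)
    state has zero probability at every node, and the root marginals equal
    the prior-weighted normalised root partials of the likelihood pass.
    """
    if not fit.converged and not force:
        raise ValueError(
            "refusing ancestral reconstruction from a non-converged fit "
            "(pass force=True to override)"
        )
    engine: DECEngine = fit.model.engine
    return _marginal_from_engine(engine, fit.params)


def _marginal_from_engine(
    engine: DECEngine, params: DECParameters
) -> AncestralReconstruction:
    tree = engine.tree
    _, partials, cache = engine._prune(params, keep=True)
    prior = engine.root_prior
    # Outside pass: F[v][s] is proportional to the probability of all data
    # outside v's subtree jointly with parental-range state s at node v.
    F: dict[int, np.ndarray] = {tree.root: prior.copy()}
    sp = engine.space
    for v in map(int, tree.postorder[::-1]):
        if tree.is_tip(v):
            continue
        c1, c2 = tree.children[v]
        M1, M2 = cache["M"][v]
        P1, P2 = cache["P"][v]
        Fv = F[v]
        w = Fv[sp.clado_parent] * sp.clado_prob
        O1 = np.zeros(sp.n_states)
        O2 = np.zeros(sp.n_states)
        np.add.at(O1, sp.clado_left, w * M2[sp.clado_right])
        np.add.at(O2, sp.clado_right, w * M1[sp.clado_left])
        for child, O, P in ((c1, O1, P1), (c2, O2, P2)):
            Fc = P.T @ O
            s = Fc.max()
            F[child] = Fc / s if s > 0 else Fc
    probs: dict[int, np.ndarray] = {}
    for v in tree.internal_nodes():
        joint = F[v] * partials[v]
        total = joint.sum()
        probs[v] = joint / total
    return AncestralReconstruction(
        method="marginal",
        tree=tree,
        masks=list(sp.masks),
        area_labels=engine.geography.labels,
        probabilities=probs,
        params=params,
    )


def symmetric_difference_cost(masks: list[int]) -> np.ndarray:
    """Step-cost matrix: number of areas in the symmetric difference."""
    K = len(masks)
    C = np.zeros((K, K))
    for i, a in enumerate(masks):
        for j, b in enumerate(masks):
            C[i, j] = popcount(a ^ b)
    return C


def sankoff_parsimony(
    tree: Phylogeny,
    tip_ranges: dict[str, int],
    n_areas: int,
    area_labels: list[str] | None = None,
    cost: np.ndarray | None = None,
    max_range_size: int | None = None,
    allow_asymmetric: bool = False,
) -> AncestralReconstruction:
    """Sankoff minimum-cost ancestral ranges with full MPR sets.

    States are the non-null ranges over ``n_areas``.  ``cost[i, j]`` is the
    step cost between state ``i`` and ``j`` in that ordering; the default
    charges one per area gained or lost.  Asymmetric cost matrices are
    rejected unless explicitly allowed (total cost then depends on the
    rooting).
    """
    masks = enumerate_ranges(n_areas, max_range_size)[1:]  # drop null
    index = {m: i for i, m in enumerate(masks)}
    K = len(masks)
    C = symmetric_difference_cost(masks) if cost is None else np.asarray(cost, float)
    if C.shape != (K, K):
        raise ValueError(f"cost matrix must be {K}x{K} for {K} range states")
    if np.any(np.diag(C) != 0):
        raise ValueError("cost matrix must have a zero diagonal")
    if not np.allclose(C, C.T):
        if not allow_asymmetric:
            raise ValueError(
                "asymmetric cost matrix rejected (pass allow_asymmetric=True)"
            )
    INF = np.inf
    S: dict[int, np.ndarray] = {}
    # inside (down) pass
    for v in map(int, tree.postorder):
        if tree.is_tip(v):
            mask = tip_ranges[tree.tip_labels[v]]
            vec = np.full(K, INF)
            vec[index[mask]] = 0.0
            S[v] = vec
        else:
            acc = np.zeros(K)
            for c in tree.children[v]:
                acc = acc + (C + S[c][None, :]).min(axis=1)
            S[v] = acc
    total = float(S[tree.root].min())
    # outside (up) pass for full MPR sets
    O: dict[int, np.ndarray] = {tree.root: np.zeros(K)}
    for v in map(int, tree.postorder[::-1]):
        if tree.is_tip(v):
            continue
        c1, c2 = tree.children[v]
        in1 = (C + S[c1][None, :]).min(axis=1)
        in2 = (C + S[c2][None, :]).min(axis=1)
        base = O[v]
        O[c1] = ((base + in2)[:, None] + C).min(axis=0)
        O[c2] = ((base + in1)[:, None] + C).min(axis=0)
    mpr: dict[int, set[int]] = {}
    for v in tree.internal_nodes():
        tot_v = O[v] + S[v]
        best = tot_v.min()
        mpr[v] = {masks[i] for i in np.flatnonzero(tot_v <= best + 1e-9)}
    labels = area_labels or [f"A{i}" for i in range(n_areas)]
    return AncestralReconstruction(
        method="parsimony",
        tree=tree,
        masks=masks,
        area_labels=labels,
        mpr_sets=mpr,
        total_cost=total,
    )


def summarize_node(
    recon: AncestralReconstruction, node: int, threshold: float = 0.5
) -> NodeSummary:
    """Resolved/unresolved call: top range(s) and their supporting mass.

    Marginal mode: resolved iff the single top range carries at least
    ``threshold`` of the posterior mass.  Parsimony mode: resolved iff the
    MPR set is a singleton.
    """
    clade = recon.tree.clade_tips(node)
    if recon.method == "marginal":
        p = recon.probabilities[node]
        top = int(np.argmax(p))
        mass = float(p[top])
        ties = [
            recon.range_label(recon.masks[i])
            for i in np.flatnonzero(p >= mass - 1e-12)
        ]
        return NodeSummary(
            node=node,
            labels=ties,
            resolved=len(ties) == 1 and mass >= threshold,
            top_mass=mass,
            clade=clade,
        )
    mprs = sorted(recon.mpr_sets[node])
    return NodeSummary(
        node=node,
        labels=[recon.range_label(m) for m in mprs],
        resolved=len(mprs) == 1,
        top_mass=1.0 / len(mprs),
        clade=clade,
    )
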