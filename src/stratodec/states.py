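"""Range states (bitmasks over areas) and DEC cladogenesis scenarios.

A geographic range is a non-empty set of occupied areas, encoded as a
bitmask over N areas; the empty mask is the absorbing "null" state reached
when a lineage goes globally extinct.  The state space is ordered
deterministically: null first, then non-null masks sorted by occupancy
count and then by numeric mask value.

At a speciation event the parental range divides between the two daughters
following the classic DEC cladogenesis set:

* a single-area parent is inherited identically by both daughters;
* a widespread parent (>= 2 areas) splits either by *vicariance* (one
  daughter a single area ``i`` of the parent, the other the remainder) or
  by *subset sympatry* (one daughter a single area ``i``, the other the
  full parental range), with all distinct ordered daughter pairs equally
  probable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "enumerate_ranges",
    "clado_distribution",
    "StateSpace",
    "popcount",
    "mask_to_labels",
    "labels_to_mask",
]


def popcount(mask: int) -> int:
    return bin(mask).count("1")


def mask_to_labels(mask: int, labels: list[str], sep: str = "+") -> str:
    """Human-readable name for a range, e.g. ``"SA+GA"``; null is ``"0"``."""
    if mask == 0:
        return "0"
    return sep.join(lab for i, lab in enumerate(labels) if mask >> i & 1)


def labels_to_mask(name: str, labels: list[str], sep: str = "+") -> int:
    if name in ("0", ""):
        return 0
    idx = {lab: i for i, lab in enumerate(labels)}
    mask = 0
    for part in name.split(sep):
        mask |= 1 << idx[part]
    return mask


def enumerate_ranges(n_areas: int, max_range_size: int | None = None) -> list[int]:
    """All range states in deterministic order: null, then by (size, mask).

    ``max_range_size`` caps occupancy to bound the 2^N state-space growth
    for many-area analyses; ``None`` means no cap.
    """
    if not (1 <= n_areas <= 16):
        raise ValueError(f"n_areas must be in 1..16, got {n_areas}")
    cap = n_areas if max_range_size is None else max_range_size
    if cap < 1:
        raise ValueError("max_range_size must be >= 1")
    masks = [m for m in range(1, 1 << n_areas) if popcount(m) <= cap]
    masks.sort(key=lambda m: (popcount(m), m))
    return [0] + masks


def clado_distribution(parent: int) -> list[tuple[tuple[int, int], float]]:
    """Ordered daughter-range pairs and probabilities for a parental range.

    Returns ``[((left, right), p), ...]`` with probabilities uniform over
    the distinct ordered scenarios and summing to one.  A null parent has
    no scenarios and is an error.
    """
    if parent == 0:
        raise ValueError("null range cannot speciate")
    size = popcount(parent)
    if size == 1:
        return [((parent, parent), 1.0)]
    singletons = [1 << i for i in range(parent.bit_length()) if parent >> i & 1]
    pairs: set[tuple[int, int]] = set()
    for s in singletons:
        rest = parent & ~s
        pairs.add((s, rest))      # vicariance
        pairs.add((rest, s))
        pairs.add((s, parent))    # subset sympatry
        pairs.add((parent, s))
    ordered = sorted(pairs)
    p = 1.0 / len(ordered)
    return [(pair, p) for pair in ordered]


@dataclass
class StateSpace:
    """Indexed range state space with precomputed cladogenesis tables.

    Attributes
    ----------
    masks : list[int]
        States in canonical order (null at index 0).
    index : dict[int, int]
        Mask -> state index.
    clado_parent, clado_left, clado_right : np.ndarray
        Flattened scenario table: scenario ``j`` has parent state
        ``clado_parent[j]`` splitting into left/right daughter states, with
        probability ``clado_prob[j]``.  Scenarios whose daughters fall
        outside a capped state space are dropped and the remaining
        probabilities renormalised per parent.
    """

    n_areas: int
    max_range_size: int | None = None

    def __post_init__(self) -> None:
        self.masks = enumerate_ranges(self.n_areas, self.max_range_size)
        self.index = {m: i for i, m in enumerate(self.masks)}
        self.n_states = len(self.masks)
        par, left, right, prob = [], [], [], []
        for i, mask in enumerate(self.masks):
            if mask == 0:
                continue
            scen = [
                ((l, r), p)
                for (l, r), p in clado_distribution(mask)
                if l in self.index and r in self.index
            ]
            total = sum(p for _, p in scen)
            for (l, r), p in scen:
                par.append(i)
                left.append(self.index[l])
                right.append(self.index[r])
                prob.append(p / total)
        self.clado_parent = np.array(par, dtype=np.intp)
        self.clado_left = np.array(left, dtype=np.intp)
        self.clado_right = np.array(right, dtype=np.intp)
        self.clado_prob = np.array(prob)
        #: indicator of non-null states, used for the root prior
        self.nonnull = np.ones(self.n_states, dtype=bool)
        self.nonnull[0] = False

    def combine_daughters(self, m_left: np.ndarray, m_right: np.ndarray) -> np.ndarray:
        """Conditional likelihoods at a node from propagated daughter partials.

        ``m_left[s]`` must be the probability of the left subtree's data
        given daughter start state ``s`` (and similarly ``m_right``); the
        result sums the cladogenesis scenarios for each parental state.
        """
        out = np.zeros(self.n_states)
        np.add.at(
            out,
            self.clado_parent,
            self.clado_prob * m_left[self.clado_left] * m_right[self.clado_right],
        )
        return out

    def tip_vector(self, mask: int) -> np.ndarray:
        if mask == 0:
            raise ValueError("observed tip range must be non-null")
        try:
            i = self.index[mask]
        except KeyError:
            raise ValueError(
                f"tip range {mask:#b} exceeds the configured range-size cap"
            ) from None
        v = np.zeros(self.n_states)
        v[i] = 1.0
        return v
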