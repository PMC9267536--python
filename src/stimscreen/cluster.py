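"""Gower dissimilarity on binary activation profiles and DIANA clustering.

Gower's coefficient on all-binary *symmetric* variables reduces to the
simple-matching distance: the fraction of compared signals on which two
stimuli disagree.  An *asymmetric* mode is also provided, in which joint
absences (0/0) are dropped from both numerator and denominator
(Jaccard-style), for the view that two stimuli failing to elicit the same
signal carries no similarity information.  Masked (MISSING) cells are
excluded pairwise in both modes.

DIANA (DIvisive ANAlysis) builds a top-down hierarchy: starting from one
cluster holding every stimulus, it repeatedly splits the cluster with the
largest diameter (maximum pairwise dissimilarity) by seeding a splinter
group with the most averagely-dissimilar member and then moving over, one
at a time, each member that is on average closer to the splinter than to
the rest, while that holds.  The height recorded for a split is the
diameter of the cluster being split, so heights are non-increasing along
every root-to-leaf path.  Ties (cluster choice, splinter seed, move
candidate) are always broken toward the lowest item index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import IncomparablePairError, StimscreenError, ValidationError
from .screen_io import ActivationMatrix

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] between stimuli."""

    items: list[str]
    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.items)
        if self.d.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape does not match items")
        if not np.isfinite(self.d).all():
            raise ValidationError("dissimilarities must be finite")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValidationError("self-dissimilarities must be 0")
        if (self.d < 0).any() or (self.d > 1 + 1e-12).any():
            raise ValidationError("dissimilarities must lie in [0, 1]")


@dataclass
class DianaNode:
    """A node of the division hierarchy.

    ``items`` are integer indices into the tree's item list; ``height`` is
    the diameter of the item set for internal nodes and 0 for leaves.
    """

    items: tuple[int, ...]
    height: float = 0.0
    children: tuple["DianaNode", "DianaNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class DivisiveTree:
    """Full DIANA hierarchy with split heights and the divisive coefficient.

    ``divisions`` lists internal nodes in the order they were split; because
    DIANA always splits the current largest-diameter cluster and diameters
    shrink under division, this order is also non-increasing in height.
    """

    items: list[str]
    root: DianaNode
    divisions: list[DianaNode] = field(repr=False)
    divisive_coefficient: float = 0.0

    def to_dict(self) -> dict:
        def rec(node: DianaNode) -> dict:
            if node.is_leaf:
                return {"item": self.items[node.items[0]], "height": 0.0}
            return {
                "height": node.height,
                "children": [rec(c) for c in node.children],
            }

        return {
            "items": self.items,
            "divisive_coefficient": self.divisive_coefficient,
            "tree": rec(self.root),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ClusterAssignment:
    """A flat k-clustering; labels 1..k numbered by first-occurring item."""

    k: int
    labels: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.labels.values())) != self.k:
            raise ValidationError("assignment does not have exactly k clusters")


def gower_binary(
    am: ActivationMatrix, mode: str = "gower_symmetric"
) -> DissimilarityMatrix:
    """Pairwise Gower dissimilarities between binary stimulus profiles.

    Parameters
    ----------
    am
        Activation matrix (usually after :func:`~stimscreen.activation.filter_matrix`).
    mode
        ``"gower_symmetric"`` (default): simple-matching distance —
        mismatches / comparable signals.  ``"gower_asymmetric"``: 0/0
        matches are excluded from both counts.

    Raises
    ------
    IncomparablePairError
        If two stimuli share no comparable signal (possible under the
        asymmetric mode or heavy masking).
    """
    if mode not in ("gower_symmetric", "gower_asymmetric"):
        raise StimscreenError(f"unknown Gower mode {mode!r}")
    x = am.calls.to_numpy(dtype=np.int8)
    obs = ~am.mask.to_numpy(dtype=bool)
    n, m = x.shape
    if n < 2 or m < 1:
        raise StimscreenError("need >= 2 stimuli and >= 1 signal for distances")
    items = list(am.calls.index)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = obs[i] & obs[j]
            if mode == "gower_asymmetric":
                comp = comp & ~((x[i] == 0) & (x[j] == 0))
            denom = int(comp.sum())
            if denom == 0:
                raise IncomparablePairError(
                    f"stimuli {items[i]!r} and {items[j]!r} share no comparable signal"
                )
            num = int(((x[i] != x[j]) & comp).sum())
            d[i, j] = d[j, i] = num / denom
    return DissimilarityMatrix(items=items, d=d, metric=mode)


# ---------------------------------------------------------------------------
# DIANA
# ---------------------------------------------------------------------------

def _split_cluster(items: tuple[int, ...], d: np.ndarray) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """One DIANA division: splinter-group procedure on ``items`` (ascending).

    Returns (splinter, remainder), each sorted ascending.
    """
    idx = np.array(items)
    sub = d[np.ix_(idx, idx)]
    n = len(idx)
    # seed: largest average dissimilarity to the other members; ties -> lowest
    # index (items are ascending, argmax returns the first maximum)
    avg = sub.sum(axis=1) / (n - 1)
    seed = int(np.argmax(avg))
    splinter = [seed]
    rest = [i for i in range(n) if i != seed]
    while len(rest) > 1:
        best_pos, best_diff = -1, 0.0
        for pos, i in enumerate(rest):
            # d(i,i)=0 contributes nothing to the sum over the member's own part
            a = sub[i, rest].sum() / (len(rest) - 1)
            b = sub[i, splinter].mean()
            diff = a - b
            if diff > best_diff:  # strict: ties keep the earlier (lower) index
                best_pos, best_diff = pos, diff
        if best_pos == -1:  # no member is on average closer to the splinter
            break
        splinter.append(rest.pop(best_pos))
    splinter_items = tuple(sorted(int(idx[i]) for i in splinter))
    rest_items = tuple(sorted(int(idx[i]) for i in rest))
    return splinter_items, rest_items


def _diameter(items: tuple[int, ...], d: np.ndarray) -> float:
    if len(items) < 2:
        return 0.0
    idx = np.array(items)
    return float(d[np.ix_(idx, idx)].max())


def diana(D: DissimilarityMatrix | np.ndarray) -> DivisiveTree:
    """Classical divisive hierarchical clustering of a dissimilarity matrix.

    Accepts a :class:`DissimilarityMatrix` or any symmetric square array with
    zero diagonal and finite non-negative entries (heights then live on that
    array's scale).
    """
    if isinstance(D, DissimilarityMatrix):
        items = list(D.items)
        d = D.d
    else:
        d = np.asarray(D, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise StimscreenError("dissimilarity input must be a square matrix")
        if not np.isfinite(d).all():
            raise ValidationError("dissimilarities must be finite")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0) or (d < 0).any():
            raise ValidationError(
                "dissimilarity matrix must be symmetric, non-negative, zero-diagonal"
            )
        items = [str(i) for i in range(d.shape[0])]
    n = len(items)
    if n < 2:
        raise StimscreenError("need at least 2 items to cluster")

    root = DianaNode(items=tuple(range(n)))
    active = [root]
    divisions: list[DianaNode] = []
    singleton_height: dict[int, float] = {}
    while True:
        splittable = [c for c in active if len(c.items) > 1]
        if not splittable:
            break
        # largest diameter; ties -> cluster containing the lowest item index
        diams = [_diameter(c.items, d) for c in splittable]
        best = max(range(len(splittable)),
                   key=lambda i: (diams[i], -min(splittable[i].items)))
        node, diam = splittable[best], diams[best]
        left, right = _split_cluster(node.items, d)
        node.height = diam
        node.children = (DianaNode(items=left), DianaNode(items=right))
        divisions.append(node)
        for child in node.children:
            if len(child.items) == 1:
                singleton_height[child.items[0]] = diam
        active.remove(node)
        active.extend(node.children)

    H = root.height
    if H > 0:
        dc = float(np.mean([1.0 - singleton_height[i] / H for i in range(n)]))
    else:
        dc = 0.0
    return DivisiveTree(items=items, root=root, divisions=divisions,
                        divisive_coefficient=dc)


def cut_tree(tree: DivisiveTree, k: int) -> ClusterAssignment:
    """Cut the division hierarchy into ``k`` flat clusters.

    The first ``k - 1`` divisions (which are the highest, in division order)
    are applied; equal split heights crossing the k-boundary are resolved by
    division order, which is logged.
    """
    n = len(tree.items)
    if not 1 <= k <= n:
        raise StimscreenError(f"k must be in [1, {n}], got {k}")
    applied = tree.divisions[: k - 1]
    if (
        0 < k - 1 < len(tree.divisions)
        and tree.divisions[k - 1].height == applied[-1].height
    ):
        logger.info(
            "tied split heights at the k=%d boundary resolved by division order", k
        )
    active: list[DianaNode] = [tree.root]
    for node in applied:
        active.remove(node)
        active.extend(node.children)
    # label clusters 1..k by their first-occurring item in input order
    active.sort(key=lambda c: min(c.items))
    labels: dict[str, int] = {}
    for lab, node in enumerate(active, start=1):
        for i in node.items:
            labels[tree.items[i]] = lab
    return ClusterAssignment(k=k, labels=labels)
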