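"""Grouping correlated variables for joint hypothesis tests.

Highly correlated variables compete for inclusion and dilute one
another's individual posterior probabilities, so the scan tests groups as
well as single variables.  Two grouping routes are provided:

* predefined — UPGMA (average-linkage) hierarchical clustering on the
  distance 1 - r^2 between variables, giving nu - 1 nested candidate
  groups; "broad clusters" (>= 20 members, mean r^2 >= 0.02 by default)
  label the tree's coarse structure, and reporting keeps only the
  smallest significant subgroup since any superset of a significant group
  is significant by definition;
* post hoc — variables whose per-draw inclusion indicators are negatively
  correlated across the posterior sample "swap in and out" for each
  other; OPTICS density clustering on the distance 1 + correlation
  recovers these interchangeable sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .glm import Dataset
from .priors import GroupQuery, PriorSpec
from .sampler import SampleStore

__all__ = [
    "GroupTree",
    "pairwise_r2",
    "upgma_tree",
    "broad_clusters",
    "smallest_significant_subgroup",
    "posthoc_groups",
    "remove_correlated",
]


def pairwise_r2(data: Dataset | np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between all columns.

    Symmetric with unit diagonal; zero-variance columns get r^2 = 0 off
    the diagonal, with a warning.
    """
    X = data.X if isinstance(data, Dataset) else np.asarray(data, dtype=float)
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance column(s): r^2 set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    r2 = np.clip(corr * corr, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return r2


@dataclass
class GroupTree:
    """Binary merge tree over nu leaves.

    Nodes 0..nu-1 are leaves; internal node nu+k is the k-th merge.
    ``merges[k] = (left, right, height)`` with heights nondecreasing.
    """

    nu: int
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if len(self.merges) != self.nu - 1:
            raise ValueError("a binary tree over nu leaves has nu-1 merges")
        self._members: dict[int, tuple[int, ...]] = {
            i: (i,) for i in range(self.nu)
        }
        for k, (a, b, _) in enumerate(self.merges):
            self._members[self.nu + k] = tuple(
                sorted(self._members[a] + self._members[b])
            )

    @property
    def n_nodes(self) -> int:
        return 2 * self.nu - 1

    def members(self, node: int) -> tuple[int, ...]:
        return self._members[node]

    def children(self, node: int) -> tuple[int, int] | None:
        if node < self.nu:
            return None
        a, b, _ = self.merges[node - self.nu]
        return a, b

    def height(self, node: int) -> float:
        return 0.0 if node < self.nu else self.merges[node - self.nu][2]

    def cophenetic(self) -> np.ndarray:
        """Matrix of merge heights at which each leaf pair first joins."""
        out = np.zeros((self.nu, self.nu))
        for k, (a, b, h) in enumerate(self.merges):
            for i in self._members[a]:
                for j in self._members[b]:
                    out[i, j] = out[j, i] = h
        return out


def upgma_tree(r2: np.ndarray) -> GroupTree:
    """Average-linkage agglomeration on the distance d = 1 - r^2.

    Naive O(nu^3) implementation with a documented deterministic
    tie-break: among pairs at the minimum distance, the one with the
    lowest (then second-lowest) cluster id merges first.  Cluster ids are
    assigned in creation order (leaves first), matching the GroupTree node
    numbering.
    """
    nu = r2.shape[0]
    if r2.shape != (nu, nu):
        raise ValueError("r2 must be square")
    D = 1.0 - np.asarray(r2, dtype=float)
    np.fill_diagonal(D, np.inf)
    # active cluster id -> (row index in the working matrix)
    active: list[int] = list(range(nu))       # cluster ids, ascending
    sizes = {i: 1 for i in range(nu)}
    work = D.copy()                            # distances between active clusters
    merges: list[tuple[int, int, float]] = []
    next_id = nu
    for _ in range(nu - 1):
        m = len(active)
        # find minimum with lowest-id tie-break: iterate in id order
        best = (math.inf, -1, -1)
        for ai in range(m):
            for bi in range(ai + 1, m):
                d = work[ai, bi]
                if d < best[0] - 1e-15:
                    best = (d, ai, bi)
        d, ai, bi = best
        a, b = active[ai], active[bi]
        # average-linkage update against every other active cluster
        sa, sb = sizes[a], sizes[b]
        new_row = (sa * work[ai, :] + sb * work[bi, :]) / (sa + sb)
        keep = [i for i in range(m) if i not in (ai, bi)]
        work = np.vstack([work[keep][:, keep],
                          new_row[keep][None, :]])
        last = np.append(new_row[keep], np.inf)
        work = np.column_stack([work, last[: work.shape[0]]])
        work[-1, :] = last[: work.shape[1]]
        work[:, -1] = last[: work.shape[0]]
        work[-1, -1] = np.inf
        active = [active[i] for i in keep] + [next_id]
        sizes[next_id] = sa + sb
        merges.append((a, b, float(d)))
        next_id += 1
    return GroupTree(nu, merges)


def broad_clusters(
    tree: GroupTree,
    r2: np.ndarray,
    min_size: int = 20,
    min_mean_r2: float = 0.02,
) -> list[tuple[int, tuple[int, ...]]]:
    """Coarse cluster labels: maximal tree nodes that (i) have at least
    ``min_size`` members, (ii) have mean pairwise r^2 >= ``min_mean_r2``,
    and (iii) still hang together below the cut height 1 - min_mean_r2.

    Under average linkage a node's merge height is 1 minus the mean r^2
    between the two subtrees it joins, so (iii) is the standard tree cut
    at the same correlation floor: without it, merging two internally
    tight but mutually uncorrelated blocks can still satisfy (ii) and a
    single node would swallow the whole structure.  Returns (node,
    members) pairs; qualifying nodes' descendants are not reported.
    """

    def mean_offdiag(members: tuple[int, ...]) -> float:
        sub = r2[np.ix_(members, members)]
        k = len(members)
        return float((sub.sum() - k) / (k * (k - 1)))

    cut = 1.0 - min_mean_r2
    out: list[tuple[int, tuple[int, ...]]] = []
    stack = [tree.n_nodes - 1]
    while stack:
        node = stack.pop()
        members = tree.members(node)
        if (
            len(members) >= min_size
            and tree.height(node) <= cut
            and mean_offdiag(members) >= min_mean_r2
        ):
            out.append((node, members))
            continue
        kids = tree.children(node)
        if kids is not None:
            stack.extend(kids)
    return sorted(out, key=lambda t: t[1])


def smallest_significant_subgroup(
    tree: GroupTree,
    store: SampleStore,
    prior: PriorSpec,
    tau: float,
) -> list[dict]:
    """Minimal tree nodes (leaves included) whose group posterior odds
    exceed tau, with every significant ancestor suppressed.

    Group posterior probabilities come from the same pooled sample as
    individual ones — the group test is a functional of the single model
    posterior, not a refit.  Returns one record per reported node with
    members, pp and log10 posterior odds.
    """
    from .inference import log_odds_from_pp  # local import avoids a cycle

    n_draws = store.n_total
    log_tau = math.log(tau)
    sig: dict[int, tuple[float, float]] = {}
    for node in range(tree.n_nodes):
        pp = store.pooled_inclusion(tree.members(node))
        log_po, _ = log_odds_from_pp(pp, n_draws)
        if log_po > log_tau:
            sig[node] = (pp, log_po)

    def has_significant_descendant(node: int) -> bool:
        kids = tree.children(node)
        if kids is None:
            return False
        stack = list(kids)
        while stack:
            k = stack.pop()
            if k in sig:
                return True
            kk = tree.children(k)
            if kk is not None:
                stack.extend(kk)
        return False

    out = []
    for node, (pp, log_po) in sorted(sig.items()):
        if has_significant_descendant(node):
            continue
        out.append(
            {
                "node": node,
                "members": tree.members(node),
                "pp": 100.0 * pp,
                "log10_po": log_po / math.log(10.0),
            }
        )
    return out


def posthoc_groups(
    store: SampleStore,
    xi: float = 0.05,
    min_samples: int = 2,
) -> list[tuple[int, ...]]:
    """Nonoverlapping groups of variables that substitute for one another.

    Computes the correlation matrix of per-draw inclusion indicators over
    the pooled sample, maps it to the distance d = 1 + corr (strongest
    negative correlation -> smallest distance) and extracts xi-clusters
    from an OPTICS density ordering.  Variables never or always included
    (zero indicator variance) are excluded with a warning.
    """
    from sklearn.cluster import OPTICS

    ind = store.indicator_matrix().astype(float)
    var = ind.var(axis=0)
    keep = np.where(var > 0)[0]
    if keep.size < ind.shape[1]:
        warnings.warn(
            f"{ind.shape[1] - keep.size} variable(s) with zero inclusion "
            "variance excluded from post-hoc grouping",
            stacklevel=2,
        )
    if keep.size < 2:
        return []
    corr = np.corrcoef(ind[:, keep], rowvar=False)
    D = np.clip(1.0 + corr, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    opt = OPTICS(metric="precomputed", xi=xi,
                 min_samples=min(min_samples, keep.size - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        labels = opt.fit(D).labels_
    groups: dict[int, list[int]] = {}
    for local, lab in enumerate(labels):
        if lab >= 0:
            groups.setdefault(int(lab), []).append(int(keep[local]))
    return [tuple(sorted(v)) for _, v in sorted(groups.items())]


def remove_correlated(
    data: Dataset,
    anchors: list[int] | tuple[int, ...],
    r2_threshold: float,
    *,
    keep_anchors: bool = True,
) -> tuple[Dataset, list[tuple[str, str]]]:
    """Drop every variable correlated at r^2 >= threshold with any anchor.

    Used to re-run a scan with a category of variables (and everything
    echoing them) excluded.  Anchors themselves are kept by default; pass
    ``keep_anchors=False`` to drop them too.  Returns the reduced dataset
    and a removal log of (name, reason) pairs.  Refuses to empty the
    design.
    """
    if r2_threshold < 0:
        raise ValueError("r2_threshold must be >= 0")
    anchors = sorted(set(int(a) for a in anchors))
    r2 = pairwise_r2(data)
    removed: list[tuple[str, str]] = []
    keep: list[int] = []
    for j in range(data.nu):
        if j in anchors:
            if keep_anchors:
                keep.append(j)
            else:
                removed.append((data.names[j], "anchor"))
            continue
        hits = [a for a in anchors if r2[j, a] >= r2_threshold]
        if hits:
            removed.append(
                (data.names[j], f"r2>={r2_threshold:g} with {data.names[hits[0]]}")
            )
        else:
            keep.append(j)
    if not keep:
        raise ValueError("removal would leave no variables")
    return (
        Dataset(data.X[:, keep], data.y, [data.names[j] for j in keep]),
        removed,
    )
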