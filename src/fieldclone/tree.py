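"""Clone phylogeny reconstruction from per-sample cluster CCFs.

Two constraints order mutation clusters into a rooted tree:

* sum (pigeonhole) rule — in every sample a parent's CCF must cover the
  summed CCFs of its children;
* crossing rule — two clusters whose CCF ordering reverses between samples
  cannot lie on one lineage and are forced to be siblings.

``build_tree`` attaches clusters greedily (largest first, deepest
compatible parent preferred, i.e. maximally nested) with backtracking, so a
consistent tree is found whenever one exists at the given tolerance.
``enumerate_consistent_trees`` is the brute-force oracle for small cases.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ROOT = "root"


class NoConsistentPhylogenyError(RuntimeError):
    pass


@dataclass
class CloneTree:
    """Rooted clone tree: cluster nodes under a germline root node."""

    parent: dict[str, str]                    # node -> parent (ROOT at top)
    ccf: dict[str, dict[str, float]]          # node -> sample -> CCF
    n_snvs: dict[str, int]
    n_indels: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.parent)

    @property
    def sample_ids(self) -> list[str]:
        first = next(iter(self.ccf.values()))
        return list(first)

    def children(self, node: str) -> list[str]:
        return sorted(n for n, p in self.parent.items() if p == node)

    def depth(self, node: str) -> int:
        d = 0
        while node != ROOT:
            node = self.parent[node]
            d += 1
        return d

    def same_topology(self, other: "CloneTree") -> bool:
        return self.parent == other.parent


def ancestry_compatible(a, b, tolerance: float = 0.05) -> str:
    """Pairwise lineage verdict from two per-sample CCF vectors.

    Returns one of ``a_ancestor_of_b``, ``b_ancestor_of_a``,
    ``siblings_forced`` (crossing: each exceeds the other somewhere) or
    ``ambiguous`` (equal within tolerance everywhere).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("CCF vectors cover different sample sets")
    a_excess = bool(np.any(a > b + tolerance))
    b_excess = bool(np.any(b > a + tolerance))
    if a_excess and b_excess:
        return "siblings_forced"
    if a_excess and np.all(a >= b - tolerance):
        return "a_ancestor_of_b"
    if b_excess and np.all(b >= a - tolerance):
        return "b_ancestor_of_a"
    return "ambiguous"


def _as_node_data(clusters) -> tuple[list[str], dict[str, np.ndarray],
                                     dict[str, int], dict[str, int], list[str]]:
    """Accepts ClusterResult-like objects (cluster_id, ccf, n_snvs, n_indels)."""
    ids, vecs, nsnv, nind = [], {}, {}, {}
    samples: list[str] | None = None
    for c in clusters:
        nid = str(c.cluster_id)
        if samples is None:
            samples = list(c.ccf)
        ids.append(nid)
        vecs[nid] = np.array([c.ccf[s] for s in samples], float)
        nsnv[nid] = c.n_snvs
        nind[nid] = getattr(c, "n_indels", 0)
    return ids, vecs, nsnv, nind, samples or []


def default_tolerance(clusters, depth: float = 50.0) -> float:
    """Two binomial standard errors of the least-supported cluster's CCF.

    The CCF of a cluster is an average of ~n_snvs allele fractions scaled by
    roughly 2, so its standard error is about
    2*sqrt(v(1-v)/(depth*n_snvs)).  Floored at 0.02 (twice the CCF grid
    step) so exact inputs are not over-constrained.
    """
    eps = 0.02
    for c in clusters:
        v = min(max(np.mean(list(c.ccf.values())) / 2, 0.01), 0.5)
        se = 2 * np.sqrt(v * (1 - v) / (depth * max(c.n_snvs, 1)))
        eps = max(eps, 2 * se)
    return float(eps)


def _check_tree(parent: dict[str, str], vecs: dict[str, np.ndarray],
                root_vec: np.ndarray, eps: float) -> bool:
    """Sum rule and ancestor dominance in every sample, within eps."""
    get = lambda n: root_vec if n == ROOT else vecs[n]
    # ancestor dominance (transitively)
    for node in parent:
        anc = parent[node]
        while anc != ROOT:
            if np.any(vecs[anc] < vecs[node] - eps):
                return False
            anc = parent[anc]
        if np.any(root_vec < vecs[node] - eps):
            return False
    # pigeonhole capacity
    kids: dict[str, list[str]] = {}
    for node, p in parent.items():
        kids.setdefault(p, []).append(node)
    for p, cs in kids.items():
        total = np.sum([vecs[c] for c in cs], axis=0)
        if np.any(total > get(p) + eps):
            return False
    return True


def build_tree(clusters, tolerance: float | None = None,
               mean_depth: float = 50.0) -> CloneTree:
    """Arrange retained clusters into a rooted tree obeying both rules.

    Clusters are attached in order of decreasing total CCF; candidate
    parents are tried deepest-first (maximally nested parsimony convention)
    with backtracking, so failure means no consistent tree exists at the
    tolerance.  On failure the tolerance is escalated once to twice its
    value with a warning; a second failure raises
    :class:`NoConsistentPhylogenyError` naming a conflicting pair.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("build_tree needs at least one cluster")
    ids, vecs, nsnv, nind, samples = _as_node_data(clusters)
    eps = default_tolerance(clusters, mean_depth) if tolerance is None else tolerance
    # germline root covers every cell; absorb cap/noise overshoot above 1
    root_vec = np.maximum(1.0, np.max(np.stack(list(vecs.values())), axis=0))

    order = sorted(ids, key=lambda i: (-vecs[i].sum(), i))

    def solve(eps: float) -> dict[str, str] | None:
        parent: dict[str, str] = {}

        def depth_of(node: str) -> int:
            d = 0
            while node != ROOT:
                node = parent[node]
                d += 1
            return d

        def attach(i: int) -> bool:
            if i == len(order):
                return True
            nid = order[i]
            placed = list(parent)
            candidates = sorted(placed, key=lambda n: (-depth_of(n), n)) + [ROOT]
            for cand in candidates:
                if cand != ROOT:
                    verdict = ancestry_compatible(vecs[cand], vecs[nid], eps)
                    if verdict not in ("a_ancestor_of_b", "ambiguous"):
                        continue
                parent[nid] = cand
                if _check_tree(parent, vecs, root_vec, eps) and attach(i + 1):
                    return True
                del parent[nid]
            return False

        return dict(parent) if attach(0) else None

    parent = solve(eps)
    if parent is None:
        log.warning("no consistent tree at tolerance %.3g; retrying at %.3g",
                    eps, 2 * eps)
        parent = solve(2 * eps)
    if parent is None:
        pair = _worst_pair(ids, vecs, 2 * eps)
        raise NoConsistentPhylogenyError(
            f"no consistent phylogeny at tolerance {2 * eps:.3g}; "
            f"conflicting clusters {pair[0]} and {pair[1]}"
        )
    return CloneTree(parent=parent,
                     ccf={i: {s: float(vecs[i][j]) for j, s in enumerate(samples)}
                          for i in ids},
                     n_snvs=nsnv, n_indels=nind)


def _worst_pair(ids, vecs, eps) -> tuple[str, str]:
    best, worst = (ids[0], ids[-1] if len(ids) > 1 else ids[0]), -1.0
    for a, b in itertools.combinations(ids, 2):
        if ancestry_compatible(vecs[a], vecs[b], eps) == "siblings_forced":
            overlap = float(np.max(vecs[a] + vecs[b] - 1))
            if overlap > worst:
                best, worst = (a, b), overlap
    return best


def enumerate_consistent_trees(clusters, tolerance: float | None = None,
                               mean_depth: float = 50.0) -> list[CloneTree]:
    """Brute-force oracle: every rooted tree satisfying both rules.

    Exhaustively enumerates parent maps; refuses more than 7 clusters
    (superexponential beyond that).
    """
    clusters = list(clusters)
    if len(clusters) > 7:
        raise ValueError("enumeration limited to 7 clusters")
    ids, vecs, nsnv, nind, samples = _as_node_data(clusters)
    eps = default_tolerance(clusters, mean_depth) if tolerance is None else tolerance
    root_vec = np.maximum(1.0, np.max(np.stack(list(vecs.values())), axis=0))

    # candidate parents per node, pruned by the pairwise verdicts
    candidates: dict[str, list[str]] = {}
    for nid in ids:
        cands = [ROOT]
        for other in ids:
            if other == nid:
                continue
            if ancestry_compatible(vecs[other], vecs[nid], eps) in (
                    "a_ancestor_of_b", "ambiguous"):
                cands.append(other)
        candidates[nid] = cands

    trees: list[CloneTree] = []
    for combo in itertools.product(*(candidates[n] for n in ids)):
        parent = dict(zip(ids, combo))
        # acyclicity
        ok = True
        for node in ids:
            seen = set()
            cur = node
            while cur != ROOT:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = parent[cur]
            if not ok:
                break
        if ok and _check_tree(parent, vecs, root_vec, eps):
            trees.append(CloneTree(
                parent=parent,
                ccf={i: {s: float(vecs[i][j]) for j, s in enumerate(samples)}
                     for i in ids},
                n_snvs=nsnv, n_indels=nind))
    return trees


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_tree(tree: CloneTree) -> tuple[str, pd.DataFrame]:
    """Newick string (branch lengths = SNV counts) plus a node table."""

    def clade(node: str) -> str:
        kids = tree.children(node)
        inner = "(" + ",".join(clade(k) for k in kids) + ")" if kids else ""
        if node == ROOT:
            return inner
        return f"{inner}{node}:{tree.n_snvs[node]}"

    newick = clade(ROOT) + ";"
    rows = []
    for node in tree.nodes:
        row = {"node": node, "parent": tree.parent[node],
               "n_snvs": tree.n_snvs[node],
               "n_indels": tree.n_indels.get(node, 0)}
        for s, v in tree.ccf[node].items():
            row[f"ccf_{s}"] = v
        rows.append(row)
    return newick, pd.DataFrame(rows)
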