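"""Temperature-indexed cluster lineages, hierarchy, and natural clusters.

As temperature rises, the single ferromagnetic cluster breaks into
subclusters and eventually into singletons.  This module turns the
per-temperature partitions of a sweep into *lineages* (the "same" cluster
followed across adjacent temperatures via Jaccard overlap), arranges the
lineages into a split hierarchy, and extracts the *natural* clusters: the
nodes that persist over a wide temperature range but whose own substructure
is only ephemeral.

Per node the tree records

* ``t_ferro`` -- length of the temperature range over which the node's
  point set stays one cluster (its lifetime, death T minus birth T);
* ``t_cl``    -- lifetime of the node's most stable child (if any);
* ``t_max``   -- temperature at which the node's members are majority
  singletons (its paramagnetic transition);
* ``s_t``     -- stability relative to the whole set (lifetime divided by
  the root span t_min..root t_max, clipped to [0, 1]).

A node is emitted as natural when it has no child of reportable size whose
lifetime reaches ``s_theta`` times the node's own lifetime -- i.e. when all
of its substructure dissolves much faster than the node itself persists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import SweepPoint
from .records import ConfigurationError, DegenerateSpectrumError, InputError


@dataclass
class TreeConfig:
    s_theta: float = 0.5
    match_jaccard: float = 0.8
    min_cluster_size: int = 2
    #: a lineage that vanishes may reappear within this many grid steps
    #: (Monte Carlo flicker near a transition) and continue as itself
    gap_tolerance: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.s_theta <= 1):
            raise ConfigurationError("s_theta must be in (0, 1]")
        if not (0 < self.match_jaccard <= 1):
            raise ConfigurationError("match_jaccard must be in (0, 1]")
        if self.min_cluster_size < 1:
            raise ConfigurationError("min_cluster_size must be >= 1")
        if self.gap_tolerance < 0:
            raise ConfigurationError("gap_tolerance must be >= 0")


@dataclass
class Lineage:
    """One cluster tracked across adjacent temperatures."""

    lineage_id: int
    members: frozenset[int]  # composition at birth (representative set)
    birth_index: int
    birth_T: float
    death_index: int
    death_T: float
    parent: int | None = None  # lineage id of the cluster it split from
    current: frozenset[int] = field(default_factory=frozenset)

    @property
    def lifetime(self) -> float:
        return self.death_T - self.birth_T


@dataclass
class ClusterNode:
    """Node of the natural-cluster tree."""

    members: frozenset[int]
    t_ferro: float
    t_cl: float | None = None
    t_max: float | None = None
    s_t: float | None = None
    is_natural: bool = False
    hierarchical_id: str = "0"
    children: list["ClusterNode"] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    def leaves(self) -> list["ClusterNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def natural_clusters(self) -> list["ClusterNode"]:
        if self.is_natural:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.natural_clusters())
        return out

    def to_dict(self) -> dict:
        return {
            "id": self.hierarchical_id,
            "size": self.size,
            "t_ferro": self.t_ferro,
            "t_cl": self.t_cl,
            "t_max": self.t_max,
            "s_t": self.s_t,
            "is_natural": self.is_natural,
            "members": sorted(self.members),
            "children": [c.to_dict() for c in self.children],
        }


def _jaccard(a: frozenset[int], b: frozenset[int]) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def track_clusters(
    sweep: Sequence[SweepPoint], config: TreeConfig | None = None
) -> list[Lineage]:
    """Follow clusters across the sweep; Jaccard >= match_jaccard means "same".

    Matching is greedy by descending Jaccard, each candidate lineage
    continuing at most one cluster.  Candidates are the lineages alive at
    the previous temperature plus those that vanished within the last
    ``gap_tolerance`` grid steps -- near a transition the Monte Carlo
    partition can flicker (split, re-merge, split again), and without the
    grace period every flicker would restart all lifetimes.  A cluster with
    no match starts a new lineage whose parent is the previous-temperature
    lineage holding the plurality of its members.  Relabeling cluster ids
    at any single temperature does not change the result (matching uses
    member sets only).
    """
    cfg = config or TreeConfig()
    if not sweep:
        raise InputError("empty sweep")

    lineages: list[Lineage] = []
    active: dict[int, frozenset[int]] = {}  # lineage id -> current members
    first = sweep[0]
    for cluster in first.partition:
        fs = frozenset(int(v) for v in cluster)
        lin = Lineage(
            lineage_id=len(lineages), members=fs, birth_index=0, birth_T=first.T,
            death_index=0, death_T=first.T, current=fs,
        )
        lineages.append(lin)
        active[lin.lineage_id] = fs

    for k in range(1, len(sweep)):
        point = sweep[k]
        new_sets = [frozenset(int(v) for v in c) for c in point.partition]
        # candidates: alive at k-1, or died within the grace period
        candidate_ids = [
            lin.lineage_id
            for lin in lineages
            if lin.death_index >= k - 1 - cfg.gap_tolerance
        ]
        candidates = []
        for ni, ns in enumerate(new_sets):
            for lid in candidate_ids:
                jac = _jaccard(ns, lineages[lid].current)
                if jac >= cfg.match_jaccard:
                    candidates.append((jac, ni, lid))
        # prefer higher overlap, then lineages alive more recently
        candidates.sort(key=lambda t: (-t[0], -lineages[t[2]].death_index, t[1]))
        matched_new: dict[int, int] = {}
        used: set[int] = set()
        for jac, ni, lid in candidates:
            if ni in matched_new or lid in used:
                continue
            matched_new[ni] = lid
            used.add(lid)

        prev_active = dict(active)
        for ni, ns in enumerate(new_sets):
            if ni in matched_new:
                lid = matched_new[ni]
                lin = lineages[lid]
                lin.death_index = k
                lin.death_T = point.T
                lin.current = ns
            else:
                # parent: previous lineage holding the plurality of members
                parent = None
                best = 0
                for plid, ps in prev_active.items():
                    overlap = len(ns & ps)
                    if overlap > best:
                        best = overlap
                        parent = plid
                lin = Lineage(
                    lineage_id=len(lineages), members=ns, birth_index=k,
                    birth_T=point.T, death_index=k, death_T=point.T,
                    parent=parent, current=ns,
                )
                lineages.append(lin)
                lid = lin.lineage_id
            active[lid] = lineages[lid].current
        # drop lineages not seen at this step from the active map
        active = {
            lid: cur
            for lid, cur in active.items()
            if lineages[lid].death_index == k
        }
    return lineages


def stability(lineage: Lineage, root_lineage: Lineage) -> float:
    """s_T = lifetime(lineage) / lifetime(root), clipped to [0, 1]."""
    if root_lineage.lifetime <= 0:
        raise DegenerateSpectrumError("root lineage has zero lifetime")
    return float(np.clip(lineage.lifetime / root_lineage.lifetime, 0.0, 1.0))


def _t_max_of(members: frozenset[int], sweep: Sequence[SweepPoint]) -> float | None:
    """First T at which more than half of ``members`` are singletons."""
    for point in sweep:
        singles = {int(c[0]) for c in point.partition if len(c) == 1}
        if len(members & singles) > len(members) / 2:
            return point.T
    return None


def extract_natural_clusters(
    lineages: Sequence[Lineage],
    config: TreeConfig | None = None,
    sweep: Sequence[SweepPoint] | None = None,
) -> ClusterNode:
    """Build the split hierarchy and flag the natural clusters.

    The root is the lineage covering the most points at the lowest
    temperature.  Children of a node are the lineages that split from it.
    A child "qualifies" as real substructure when it has at least
    ``min_cluster_size`` members and its lifetime is at least
    ``s_theta`` times the node's own lifetime; a node with no qualifying
    child is a natural cluster (right-branch boxes of the tree rendering),
    otherwise extraction recurses into its qualifying children and the
    non-qualifying remainder forms the residual (left branch).
    """
    cfg = config or TreeConfig()
    if not lineages:
        raise InputError("no lineages")

    by_parent: dict[int | None, list[Lineage]] = {}
    for lin in lineages:
        by_parent.setdefault(lin.parent, []).append(lin)

    roots = by_parent.get(None, [])
    root_lin = max(roots, key=lambda l: len(l.members))

    # root span for s_t: t_min .. root paramagnetic melt (fallback: sweep end)
    t_start = root_lin.birth_T
    root_t_max = _t_max_of(root_lin.members, sweep) if sweep is not None else None
    if root_t_max is None:
        root_t_max = max(l.death_T for l in lineages)
    root_span = max(root_t_max - t_start, 1e-300)

    def build(lin: Lineage, hid: str) -> ClusterNode:
        kids = sorted(
            by_parent.get(lin.lineage_id, []),
            key=lambda l: (-len(l.members), l.birth_index),
        )
        node = ClusterNode(
            members=lin.members,
            t_ferro=lin.lifetime,
            t_cl=max((k.lifetime for k in kids), default=None),
            t_max=_t_max_of(lin.members, sweep) if sweep is not None else None,
            s_t=float(np.clip(lin.lifetime / root_span, 0.0, 1.0)),
            hierarchical_id=hid,
        )
        qualifying = [
            k
            for k in kids
            if len(k.members) >= cfg.min_cluster_size
            and k.lifetime >= cfg.s_theta * lin.lifetime
        ]
        if not qualifying:
            node.is_natural = True
            return node
        for ci, k in enumerate(qualifying):
            child_id = f"{hid} {ci + 1}" if hid != "0" else str(ci + 1)
            node.children.append(build(k, child_id))
        return node

    return build(root_lin, "0")


def natural_leaf_labels(tree: ClusterNode, n_points: int) -> np.ndarray:
    """Point labels from the natural clusters; unassigned points get unique
    negative labels (each its own residual singleton)."""
    labels = np.full(n_points, -1, dtype=int)
    for k, node in enumerate(tree.natural_clusters()):
        for v in node.members:
            labels[v] = k
    neg = -1
    for v in range(n_points):
        if labels[v] == -1:
            labels[v] = neg
            neg -= 1
    return labels


def first_split_index(sweep: Sequence[SweepPoint]) -> int | None:
    """Index of the first sweep point whose partition has more than one
    non-singleton-dominated cluster (i.e. the root's first split)."""
    for k, point in enumerate(sweep):
        if point.n_clusters > 1:
            return k
    return None


def membership_report(
    tree: ClusterNode, class_labels: Sequence[str | None] | None = None
) -> pd.DataFrame:
    """Flat per-node table: id, size, T statistics, members, composition.

    ``class_labels[i]`` is the class of point i (0-based); when given, one
    count column per class is appended.
    """
    rows = []

    def visit(node: ClusterNode) -> None:
        row = {
            "cluster": node.hierarchical_id,
            "size": node.size,
            "t_ferro": node.t_ferro,
            "t_cl": node.t_cl,
            "s_t": node.s_t,
            "is_natural": node.is_natural,
            "members": " ".join(str(v + 1) for v in sorted(node.members)),
        }
        if class_labels is not None:
            classes = sorted({c for c in class_labels if c is not None})
            for cname in classes:
                row[f"n_{cname}"] = sum(
                    1 for v in node.members if class_labels[v] == cname
                )
        rows.append(row)
        for c in node.children:
            visit(c)

    visit(tree)
    return pd.DataFrame(rows)


def write_tree(tree: ClusterNode, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree.to_dict(), indent=2, sort_keys=True))


def render_tree(tree: ClusterNode) -> str:
    """Plain-text rendering of the tree boxes (size, T stats, naturals marked)."""
    lines: list[str] = []

    def visit(node: ClusterNode, depth: int) -> None:
        tag = " *natural*" if node.is_natural else ""
        t_cl = f" T_cl={node.t_cl:.6g}" if node.t_cl is not None else ""
        s_t = f" s_T={node.s_t:.6g}" if node.s_t is not None else ""
        lines.append(
            "  " * depth
            + f"[{node.hierarchical_id}] size={node.size} "
            + f"T_ferro={node.t_ferro:.6g}{t_cl}{s_t}{tag}"
        )
        for c in node.children:
            visit(c, depth + 1)

    visit(tree, 0)
    return "\n".join(lines)
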