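"""Segmentation of individual molecular clusters.

Density-based segmentation of SMLM point sets:

* DBSCAN — a molecule is a *core* of a cluster when at least ``k``
  molecules (counting itself) fall within its ε-neighbourhood; non-core
  molecules inside a core's neighbourhood are *edge* molecules, the rest
  *noise*.  Simple and fast but needs well-chosen (k, ε) and a homogeneous
  cluster density.
* OPTICS — orders molecules by density reachability, requiring only a
  minimum cluster size.  Clusters appear as valleys in the reachability
  distance (RD) plot and are extracted either with a static RD threshold
  (homogeneous densities) or by recursive hierarchical segmentation of the
  RD plot at its peaks, which also resolves nested structures such as
  intraluminal vesicles inside multivesicular bodies.

Cross-channel composition of segmented clusters is quantified by taking
the convex hull of a cluster and counting the molecules of another channel
inside it.

Clusters whose estimated radius is at or below the localization precision
of the microscope are flagged: repeat detections of a single fluorophore
masquerade as clusters at exactly that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .tables import LocalizationTable

__all__ = [
    "NOISE",
    "ClusterLabeling",
    "ReachabilityProfile",
    "ClusterNode",
    "ClusterTree",
    "dbscan",
    "dbscan_parameter_sweep",
    "optics_order",
    "extract_clusters_static_rd",
    "hier_segment_rd",
    "cluster_hull_density",
    "flag_subresolution_clusters",
]

#: Sentinel label for molecules outside any cluster.
NOISE = -1


@dataclass
class ClusterLabeling:
    """Per-molecule cluster assignment.

    ``labels`` holds a cluster id per molecule with ``NOISE`` (−1) for
    unclustered molecules; ``roles`` is ``"core"``, ``"edge"`` or
    ``"noise"`` per molecule.
    """

    labels: np.ndarray
    roles: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=NOISE) + 1)

    @property
    def noise_fraction(self) -> float:
        return float(np.mean(self.labels == NOISE))

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def dbscan(table: LocalizationTable, k: int, eps: float) -> ClusterLabeling:
    """Density-based clustering with neighbourhood size ε and minimum k.

    A molecule is core when its ε-neighbourhood holds ≥ k molecules
    *including itself* (the same convention as scikit-learn's
    ``min_samples``).  Clusters are grown depth-first from unvisited core
    molecules in ascending index order, which makes edge-molecule
    assignment deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    n = table.n
    tree = cKDTree(table.coords)
    neighborhoods = tree.query_ball_point(table.coords, eps)
    core = np.array([len(nb) >= k for nb in neighborhoods])
    labels = np.full(n, NOISE, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        labels[i] = cluster
        stack = [i]
        while stack:
            p = stack.pop()
            if core[p]:
                for q in neighborhoods[p]:
                    if labels[q] == NOISE:
                        labels[q] = cluster
                        if core[q]:
                            stack.append(q)
        cluster += 1
    roles = np.where(core, "core",
                     np.where(labels != NOISE, "edge", "noise")).astype(object)
    return ClusterLabeling(labels=labels, roles=roles,
                           params={"k": k, "eps": eps})


def dbscan_parameter_sweep(table: LocalizationTable,
                           k_range: Iterable[int],
                           eps_range: Iterable[float]) -> list[dict]:
    """Summaries over a (k, ε) grid to guide parameter selection.

    Inappropriate (k, ε) over- or under-estimate cluster composition, so
    the choice is usually made by sweeping — classically k over 5–200 in
    steps of 5 and ε over 100–1000 nm in steps of 100 — and inspecting the
    resulting cluster counts and noise fractions.
    """
    k_range, eps_range = list(k_range), list(eps_range)
    if not k_range or not eps_range:
        raise ValueError("parameter ranges must be non-empty")
    out = []
    for k in k_range:
        for eps in eps_range:
            lab = dbscan(table, k=k, eps=eps)
            out.append({"k": k, "eps": eps,
                        "n_clusters": lab.n_clusters,
                        "noise_fraction": lab.noise_fraction})
    return out


@dataclass
class ReachabilityProfile:
    """OPTICS output: processing order with core/reachability distances.

    ``reachability[j]`` is the RD of the molecule at ordered position j
    (``inf`` for the first point of each connected processing chain);
    ``core_distance`` is indexed by molecule, not by position.  The RD plot
    is ``reachability`` against position.
    """

    ordering: np.ndarray
    reachability: np.ndarray      # per ordered position, nm
    core_distance: np.ndarray     # per molecule index, nm
    min_cluster_size: int

    @property
    def n(self) -> int:
        return self.ordering.size

    def rd_of_molecule(self, i: int) -> float:
        pos = int(np.flatnonzero(self.ordering == i)[0])
        return float(self.reachability[pos])


def optics_order(table: LocalizationTable, min_cluster_size: int
                 ) -> ReachabilityProfile:
    """Canonical OPTICS ordering of the molecules (no ε cap).

    The core distance of a molecule is the distance to its k-th closest
    molecule, counting the molecule itself as the first (k =
    ``min_cluster_size``).  Processing repeatedly expands the unprocessed
    molecule with the smallest tentative reachability
    ``RD(q) = max(core_distance(p), d(p, q))`` over processed expanders p,
    breaking ties toward the lowest original index.  O(n²), adequate for
    per-ROI molecule counts.
    """
    n = table.n
    k = int(min_cluster_size)
    if k < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if n <= k:
        raise ValueError("table must contain more than min_cluster_size "
                         "molecules")
    coords = table.coords
    tree = cKDTree(coords)
    # distance to the k-th closest including self = column k-1 of a k-query
    core_dist = tree.query(coords, k=k)[0][:, k - 1]

    processed = np.zeros(n, dtype=bool)
    tentative = np.full(n, np.inf)
    ordering = np.empty(n, dtype=int)
    reachability = np.empty(n, dtype=float)

    for pos in range(n):
        candidates = np.flatnonzero(~processed)
        best = candidates[np.argmin(tentative[candidates])]  # ties → low idx
        ordering[pos] = best
        reachability[pos] = tentative[best]
        processed[best] = True
        d = np.linalg.norm(coords[~processed] - coords[best], axis=1)
        new_rd = np.maximum(core_dist[best], d)
        idx = np.flatnonzero(~processed)
        improved = new_rd < tentative[idx]
        tentative[idx[improved]] = new_rd[improved]
    return ReachabilityProfile(ordering=ordering, reachability=reachability,
                               core_distance=core_dist,
                               min_cluster_size=k)


def extract_clusters_static_rd(profile: ReachabilityProfile,
                               rd_threshold: float) -> ClusterLabeling:
    """Extract clusters from the RD plot with a static threshold.

    Clusters are the valleys of the ordered RD plot: maximal runs of
    positions with RD ≤ threshold, bounded by above-threshold peaks.  A
    bounding peak whose own core distance is ≤ threshold seeds the next
    valley (it is the first molecule of that cluster, reached from
    outside); otherwise it is noise.  Runs shorter than the profile's
    minimum cluster size are discarded as noise.

    A static threshold only works when cluster density is homogeneous:
    valley depth tracks cluster density, so mixed-density images need the
    hierarchical segmentation instead.
    """
    if rd_threshold <= 0:
        raise ValueError("rd_threshold must be > 0")
    n = profile.n
    labels = np.full(n, NOISE, dtype=int)
    runs: list[list[int]] = []
    current: list[int] = []
    for pos in range(n):
        mol = int(profile.ordering[pos])
        if profile.reachability[pos] <= rd_threshold:
            current.append(mol)
        else:
            if current:
                runs.append(current)
            # an above-threshold point with a small core distance starts
            # the next valley rather than being a bare separator
            current = [mol] if profile.core_distance[mol] <= rd_threshold \
                else []
    if current:
        runs.append(current)
    cluster = 0
    for run in runs:
        if len(run) >= profile.min_cluster_size:
            labels[run] = cluster
            cluster += 1
    roles = np.where(labels == NOISE, "noise", "core").astype(object)
    return ClusterLabeling(labels=labels, roles=roles,
                           params={"rd_threshold": rd_threshold,
                                   "min_cluster_size":
                                       profile.min_cluster_size})


@dataclass
class ClusterNode:
    """A segment [start, end) of the ordered RD plot."""

    start: int
    end: int
    peak_rd: float
    mean_rd: float
    children: list = field(default_factory=list)
    parent: Optional["ClusterNode"] = None
    split_position: Optional[int] = None   # ordered position of the split peak
    discarded: bool = False                # too small / not below its peak

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d, node = d + 1, node.parent
        return d


@dataclass
class ClusterTree:
    """Hierarchical segmentation of an RD plot into nested clusters."""

    root: ClusterNode
    profile: ReachabilityProfile

    def leaves(self) -> list[ClusterNode]:
        """Deepest retained (non-discarded) segments — the reported clusters."""
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.discarded:
                continue
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(node.children)
        return sorted(out, key=lambda s: s.start)

    def nodes(self) -> list[ClusterNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def members(self, node: ClusterNode) -> np.ndarray:
        """Molecule indices of a segment (split peaks of ancestors excluded)."""
        return self.profile.ordering[node.start:node.end]

    def leaf_labeling(self) -> ClusterLabeling:
        """Per-molecule labels with each reported leaf as one cluster."""
        labels = np.full(self.profile.n, NOISE, dtype=int)
        for lab, leaf in enumerate(self.leaves()):
            labels[self.members(leaf)] = lab
        roles = np.where(labels == NOISE, "noise", "core").astype(object)
        return ClusterLabeling(labels=labels, roles=roles,
                               params={"hierarchical": True})


def _segment_stats(rd: np.ndarray, start: int, end: int) -> tuple[float, float]:
    vals = rd[start:end]
    finite = vals[np.isfinite(vals)]
    peak = float(finite.max()) if finite.size else np.inf
    mean = float(finite.mean()) if finite.size else np.inf
    return peak, mean


def hier_segment_rd(profile: ReachabilityProfile, min_cluster_size: int,
                    split_significance: float = 0.75) -> ClusterTree:
    """Recursive hierarchical segmentation of the RD plot at its peaks.

    Each segment is split at its highest interior peak, the peak itself
    belonging to no child.  A resulting child segment is *retained* when
    it holds at least ``min_cluster_size`` molecules and its mean RD is ≤
    ``split_significance`` × the split-peak RD (a segment whose mean
    approaches the bounding peak is not a separate feature); retained
    children are segmented recursively, while failing children are kept
    in the tree but marked discarded and not recursed.  Peaks are tried
    in decreasing RD order and a split stands as soon as it retains at
    least one child; a segment with no such peak is a leaf.  The
    non-discarded leaves are the reported clusters, with nested
    sub-clusters reachable through parent links — resolving, e.g.,
    vesicles nested inside larger bodies of differing density that a
    static RD cut cannot capture.
    """
    if not 0 < split_significance < 1:
        raise ValueError("split_significance must be in (0, 1)")
    rd = profile.reachability
    n = profile.n

    def make_node(start: int, end: int,
                  parent: Optional[ClusterNode]) -> ClusterNode:
        # position `start`'s RD describes entry from outside the segment,
        # so statistics and peaks use strictly later positions
        peak, mean = _segment_stats(rd, start + 1, end)
        return ClusterNode(start=start, end=end, peak_rd=peak,
                           mean_rd=mean, parent=parent)

    def child_ok(s: int, e: int, peak_rd: float) -> bool:
        if e - s < min_cluster_size:
            return False
        _, child_mean = _segment_stats(rd, s + 1, e)
        return child_mean <= split_significance * peak_rd

    root = make_node(0, n, None)
    stack = [root]
    while stack:
        node = stack.pop()
        start, end = node.start, node.end
        interior = np.arange(start + 1, end)
        if interior.size == 0:
            continue
        order = interior[np.argsort(rd[interior], kind="stable")[::-1]]
        for p in order:
            peak_rd = rd[p]
            if not np.isfinite(peak_rd):
                continue
            sides = ((start, int(p)), (int(p) + 1, end))
            valid = [child_ok(s, e, peak_rd) for s, e in sides]
            if not any(valid):
                continue
            node.split_position = int(p)
            for (s, e), ok in zip(sides, valid):
                child = make_node(s, e, node)
                node.children.append(child)
                if ok:
                    stack.append(child)
                else:
                    child.discarded = True
            break
    return ClusterTree(root=root, profile=profile)


def flag_subresolution_clusters(labeling: ClusterLabeling,
                                table: LocalizationTable,
                                precision: float) -> dict[int, bool]:
    """Flag clusters whose radius is at or below the microscope precision.

    Repeat detections of a single fluorophore form apparent clusters whose
    size equals the localization precision, so any cluster with an RMS
    radius ≤ ``precision`` should be treated as a sampling artefact rather
    than a molecular assembly.  Returns ``{label: flagged}``.
    """
    out = {}
    for label in range(labeling.n_clusters):
        pts = table.xy[labeling.members(label)]
        centroid = pts.mean(axis=0)
        rms_radius = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2,
                                                  axis=1))))
        out[label] = rms_radius <= precision
    return out


def cluster_hull_density(cluster_points: LocalizationTable,
                         other_channel: LocalizationTable
                         ) -> tuple[float, int, float]:
    """Convex-hull area of a cluster and other-channel content within it.

    Returns ``(area nm², count, density nm⁻²)`` where count is the number
    of other-channel molecules inside or on the hull.  For DBSCAN clusters
    pass the edge molecules (or all members) of one cluster.
    """
    if cluster_points.n < 3:
        raise ValueError("need >= 3 cluster points for a hull")
    try:
        hull = ConvexHull(cluster_points.xy)
    except Exception as exc:
        raise ValueError(f"degenerate hull: {exc}") from exc
    area = float(hull.volume)  # 2-D: volume is the area
    # boundary-inclusive containment via the hull's facet inequalities
    pts = other_channel.xy
    a, b = hull.equations[:, :2], hull.equations[:, 2]
    inside = np.all(pts @ a.T + b <= 1e-9, axis=1)
    count = int(inside.sum())
    return area, count, count / area
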