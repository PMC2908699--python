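"""The "Divide" phase: decompose a binding-site collection into submotifs.

Three clustering routes are provided and compared:

* :func:`pfcm` — possibilistic fuzzy c-means on the one-hot feature matrix.
  Memberships are possibilistic (each in [0, 1], *not* constrained to sum
  to 1 across clusters), so outliers can weakly belong to everything.
* :func:`agglomerative_divide` — single-linkage hierarchical clustering cut
  by the inconsistency coefficient.
* :func:`subtractive_divide` — iterative extraction of the densest
  PWM-recoverable subset until the classification measure drops to chance.

Multiple optimal cluster counts are kept (Xie–Beni index within a relative
tolerance of its minimum); the pooled clusters from all selected runs are
organized into a general→specific submotif hierarchy by a hypergeometric
overlap test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom

from .errors import ConfigurationError, SeparationZeroError, ValidationError
from .seqio import FeatureMatrix, SiteCollection

# ---------------------------------------------------------------------------
# possibilistic fuzzy c-means


@dataclass
class FuzzyPartition:
    """Result of a possibilistic fuzzy c-means run.

    ``memberships[i, j]`` is the degree of membership of site ``j`` in
    cluster ``i``; column sums are not constrained to 1.
    """

    memberships: np.ndarray  # (c, n)
    centroids: np.ndarray  # (c, d)
    eta: np.ndarray  # (c,)
    fuzzifier: float
    iterations_run: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


def _possibilistic_memberships(
    d2: np.ndarray, eta: np.ndarray, m: float
) -> np.ndarray:
    """u = 1 / (1 + (d^2 / eta) ** (1/(m-1))), with u = 1 at distance 0."""
    expo = 1.0 / (m - 1.0)
    ratio = d2 / eta[:, None]
    with np.errstate(divide="ignore"):
        u = 1.0 / (1.0 + ratio**expo)
    u[d2 == 0.0] = 1.0
    return u


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Probabilistic fuzzy c-means memberships (columns sum to 1)."""
    expo = 1.0 / (m - 1.0)
    d2 = np.maximum(d2, 1e-12)
    inv = d2 ** (-expo)
    return inv / inv.sum(axis=0, keepdims=True)


def _update_centroids(u: np.ndarray, X: np.ndarray, m: float) -> np.ndarray:
    w = u**m
    return (w @ X) / np.maximum(w.sum(axis=1, keepdims=True), 1e-300)


def _init_centroids(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """Seed centroids from c randomly chosen distinct data rows."""
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    if uniq.shape[0] >= c:
        pick = rng.choice(uniq.shape[0], size=c, replace=False)
        return uniq[pick].astype(float)
    # degenerate: fewer distinct rows than clusters; duplicates unavoidable
    pick = rng.choice(X.shape[0], size=c, replace=False)
    return X[pick].astype(float)


def pfcm(
    features: FeatureMatrix,
    c: int,
    m: float = 2.0,
    eta: float | str | np.ndarray = 1.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
) -> FuzzyPartition:
    """Possibilistic fuzzy c-means on a one-hot feature matrix.

    Parameters
    ----------
    eta
        Per-cluster bandwidth.  A scalar (the published initialization is
        1) is used as-is for every cluster.  The string ``"auto"``
        estimates ``eta_i`` from a seeded hard k-means pre-pass as the
        mean within-cluster squared distance, which puts the bandwidth on
        the data's own distance scale (membership 0.5 then falls at the
        typical within-cluster radius).

    Notes
    -----
    Iteration stops after ``max_iter`` sweeps or when the largest centroid
    movement falls below ``tol``.  Identical seeds give identical output.
    """
    X = np.asarray(features.data, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise ConfigurationError("empty feature matrix")
    if c < 1:
        raise ConfigurationError(f"cluster count must be >= 1, got {c}")
    if c > n:
        raise ConfigurationError(f"cluster count {c} exceeds number of sites {n}")
    if m <= 1:
        raise ConfigurationError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    V = _init_centroids(X, c, rng)

    guard_collapse = False
    if isinstance(eta, str):
        if eta not in ("auto", "auto-max"):
            raise ConfigurationError(f"unknown eta policy {eta!r}")
        V, eta_vec = _auto_bandwidth(X, V, m, max_iter, tol, policy=eta)
        # data-scaled bandwidths make the coincident-cluster failure likely;
        # a fixed scalar eta keeps memberships local and is left unguarded
        guard_collapse = True
    else:
        eta_vec = np.broadcast_to(np.asarray(eta, dtype=float), (c,)).copy()
        if (eta_vec <= 0).any():
            raise ConfigurationError("eta must be positive")

    def _min_sep(V):
        if V.shape[0] < 2:
            return np.inf
        s = cdist(V, V, "sqeuclidean")
        np.fill_diagonal(s, np.inf)
        return s.min()

    # Possibilistic updates are prone to the coincident-cluster failure:
    # every centroid drifts to the global mean.  The fixed-point iteration
    # is therefore guarded — when the minimum centroid separation falls
    # below a fraction of its initial value the last stable state is kept.
    sep0 = _min_sep(V)
    guard = 0.25 * sep0
    converged = False
    it = 0
    u = _possibilistic_memberships(cdist(X, V, "sqeuclidean").T, eta_vec, m)
    for it in range(1, max_iter + 1):
        V_new = _update_centroids(u, X, m)
        if (
            guard_collapse
            and np.isfinite(sep0)
            and sep0 > 0
            and _min_sep(V_new) < guard
        ):
            break  # incipient collapse: keep the previous centroids
        shift = np.abs(V_new - V).max()
        V = V_new
        u = _possibilistic_memberships(cdist(X, V, "sqeuclidean").T, eta_vec, m)
        if shift < tol:
            converged = True
            break

    # duplicate centroids signal a degenerate run, not an error
    if c > 1:
        sep = cdist(V, V, "sqeuclidean")
        np.fill_diagonal(sep, np.inf)
        if sep.min() < 1e-12:
            converged = False

    return FuzzyPartition(
        memberships=u,
        centroids=V,
        eta=eta_vec,
        fuzzifier=m,
        iterations_run=it,
        converged=converged,
    )


def _auto_bandwidth(X, V, m, max_iter, tol, policy: str = "auto"):
    """Hard k-means pre-pass supplying centroids and per-cluster bandwidths.

    A probabilistic fuzzy pre-pass collapses centroids on weakly separated
    one-hot data, so the bandwidths are taken from a plain Lloyd iteration
    started at the same seeded centroids.  ``policy="auto"`` sets ``eta_i``
    to the mean within-cluster squared distance (the scale the validity
    index compares well at); ``"auto-max"`` uses the largest within-cluster
    squared distance, so the hard 0.5 membership cut retains the whole
    pre-pass cluster — the right bandwidth for cluster extraction.
    """
    for _ in range(max_iter):
        labels = cdist(X, V, "sqeuclidean").argmin(axis=1)
        V_new = V.copy()
        for i in range(V.shape[0]):
            mask = labels == i
            if mask.any():
                V_new[i] = X[mask].mean(axis=0)
        if np.abs(V_new - V).max() < tol:
            V = V_new
            break
        V = V_new
    d2 = cdist(X, V, "sqeuclidean")
    labels = d2.argmin(axis=1)
    own = d2[np.arange(X.shape[0]), labels]
    # 1.5 x max leaves slack for boundary sites after the possibilistic
    # refinement shifts centroids slightly
    agg = (lambda v: 1.5 * float(v.max())) if policy == "auto-max" else (
        lambda v: float(v.mean())
    )
    overall = agg(own) if own.size else 1.0
    eta = np.empty(V.shape[0])
    for i in range(V.shape[0]):
        mask = labels == i
        eta[i] = agg(d2[mask, i]) if mask.any() else overall
    eta = np.maximum(eta, max(overall, 1e-6) * 0.05)
    return V, eta


# ---------------------------------------------------------------------------
# model-order selection


def xie_beni(features: FeatureMatrix, partition: FuzzyPartition) -> float:
    """Compactness-over-separation validity index (smaller is better).

    ``sum_ij u_ij^m d^2(x_j, v_i) / (n * min_{i != k} ||v_i - v_k||^2)``.
    """
    X = np.asarray(features.data, dtype=float)
    V = partition.centroids
    if V.shape[0] < 2:
        raise ConfigurationError("Xie-Beni index needs at least 2 centroids")
    sep = cdist(V, V, "sqeuclidean")
    np.fill_diagonal(sep, np.inf)
    min_sep = sep.min()
    if min_sep < 1e-12:
        raise SeparationZeroError("coincident centroids: separation is zero")
    d2 = cdist(X, V, "sqeuclidean").T
    compact = float((partition.memberships**partition.fuzzifier * d2).sum())
    return compact / (X.shape[0] * min_sep)


def select_cluster_numbers(
    features: FeatureMatrix,
    c_range,
    runs_per_c: int = 5,
    seed: int = 0,
    rel_tol: float = 0.05,
    m: float = 2.0,
    eta: float | str = "auto",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[int]:
    """All cluster counts whose best Xie-Beni index is near-optimal.

    Every ``c`` whose best index over ``runs_per_c`` restarts lies within
    ``rel_tol`` (relative) of the global minimum is returned — the method
    deliberately keeps multiple optimal partitions.
    """
    c_range = sorted(set(int(c) for c in c_range))
    if not c_range:
        raise ConfigurationError("empty c_range")
    n = features.n_sites
    if any(c < 2 or c > n - 1 for c in c_range):
        raise ConfigurationError(f"c_range must lie within [2, {n - 1}]")
    best: dict[int, float] = {}
    rng = np.random.default_rng(seed)
    for c in c_range:
        vals = []
        for _ in range(runs_per_c):
            run_seed = int(rng.integers(0, 2**31 - 1))
            part = pfcm(
                features, c, m=m, eta=eta, max_iter=max_iter, tol=tol, seed=run_seed
            )
            try:
                vals.append(xie_beni(features, part))
            except SeparationZeroError:
                continue
        if vals:
            best[c] = min(vals)
    if not best:
        raise ConfigurationError("no valid partition for any candidate c")
    global_min = min(best.values())
    return sorted(c for c, v in best.items() if v <= global_min * (1.0 + rel_tol))


# ---------------------------------------------------------------------------
# clusters, hypergeometric overlap, hierarchy


@dataclass(frozen=True)
class Cluster:
    """Hard cluster of site ids extracted from one clustering run."""

    member_ids: frozenset[str]
    source: str = "pfcm"
    label: str = ""

    @property
    def size(self) -> int:
        return len(self.member_ids)


def partition_to_clusters(
    partition: FuzzyPartition,
    site_ids: list[str],
    cut: float = 0.5,
    min_size: int = 2,
    source: str = "pfcm",
) -> list[Cluster]:
    """Hard clusters via a possibilistic membership cut (default 0.5)."""
    ids = np.asarray(site_ids)
    out = []
    for i in range(partition.n_clusters):
        members = frozenset(ids[partition.memberships[i] >= cut])
        if len(members) >= min_size:
            out.append(Cluster(member_ids=members, source=source))
    return out


def hypergeom_overlap(p: int, h: int, n: int, g: int) -> float:
    """Upper-tail probability of observing >= p shared members.

    With ``h`` draws from a population of ``g`` containing ``n`` marked
    elements, returns ``P(X >= p)`` under the hypergeometric distribution.
    Lower values indicate stronger association between the two clusters.
    """
    if not (0 <= p <= min(h, n) <= g) or h > g or n > g:
        raise ValidationError(
            f"inconsistent counts p={p}, h={h}, n={n}, g={g}"
        )
    if p == 0:
        return 1.0
    return float(hypergeom.sf(p - 1, g, n, h))


@dataclass
class TreeNode:
    """One submotif family in the hierarchy."""

    node_id: str
    member_ids: frozenset[str]
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    source: str = ""
    pwm: object | None = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class SubmotifTree:
    """Hierarchy of submotif clusters rooted at the all-sites single motif."""

    nodes: dict[str, TreeNode]
    root: str

    def children_of(self, node_id: str) -> list[TreeNode]:
        return [self.nodes[c] for c in self.nodes[node_id].children]

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if not n.children]

    def submotif_nodes(self) -> list[TreeNode]:
        """All nodes except the root, in id order."""
        return [n for k, n in sorted(self.nodes.items()) if k != self.root]

    def ancestors(self, node_id: str) -> list[str]:
        out = []
        cur = self.nodes[node_id].parent
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out

    def most_general_family(self, node_id: str) -> str:
        """The ancestor immediately below the root (or the node itself)."""
        cur = node_id
        while (
            self.nodes[cur].parent is not None
            and self.nodes[cur].parent != self.root
        ):
            cur = self.nodes[cur].parent
        return cur

    def is_acyclic(self) -> bool:
        for node_id in self.nodes:
            seen = {node_id}
            cur = self.nodes[node_id].parent
            while cur is not None:
                if cur in seen:
                    return False
                seen.add(cur)
                cur = self.nodes[cur].parent
        return True

    def to_json(self) -> str:
        payload = {
            "root": self.root,
            "nodes": {
                k: {
                    "members": sorted(n.member_ids),
                    "parent": n.parent,
                    "children": list(n.children),
                    "source": n.source,
                }
                for k, n in self.nodes.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SubmotifTree":
        payload = json.loads(text)
        nodes = {
            k: TreeNode(
                node_id=k,
                member_ids=frozenset(v["members"]),
                parent=v["parent"],
                children=list(v["children"]),
                source=v.get("source", ""),
            )
            for k, v in payload["nodes"].items()
        }
        return cls(nodes=nodes, root=payload["root"])


def build_hierarchy(
    clusters: list[Cluster],
    all_site_ids,
    alpha_hier: float = 0.01,
) -> SubmotifTree:
    """Organize pooled clusters into a general→specific forest under a root.

    Cluster A becomes the parent of B when their overlap is significant
    (hypergeometric tail probability below ``alpha_hier``) and ``|B| <=
    |A|``; among significant candidates each node keeps its *smallest*
    parent, which prunes transitive-redundant edges.  Clusters with no
    significant parent attach directly to the root (all sites).
    """
    all_ids = frozenset(all_site_ids)
    g = len(all_ids)
    # deterministic ordering: big to small, ties broken by member content
    ordered = sorted(
        clusters, key=lambda c: (-c.size, tuple(sorted(c.member_ids)))
    )
    root = TreeNode(node_id="S00", member_ids=all_ids, source="root")
    nodes = {"S00": root}
    labels = {}
    for k, cl in enumerate(ordered, start=1):
        labels[k] = f"S{k:02d}"
        nodes[labels[k]] = TreeNode(
            node_id=labels[k], member_ids=cl.member_ids, source=cl.source
        )
    for k, cl in enumerate(ordered, start=1):
        best_parent = "S00"
        best_size = g + 1
        for j, other in enumerate(ordered, start=1):
            if j == k or other.size < cl.size:
                continue
            if other.size == cl.size and j > k:
                continue  # equal sizes: only earlier clusters may parent
            p = len(cl.member_ids & other.member_ids)
            try:
                pi = hypergeom_overlap(p, cl.size, other.size, g)
            except ValidationError:
                continue
            if pi < alpha_hier and other.size < best_size:
                best_parent = labels[j]
                best_size = other.size
        nodes[labels[k]].parent = best_parent
        nodes[best_parent].children.append(labels[k])
    return SubmotifTree(nodes=nodes, root="S00")


# ---------------------------------------------------------------------------
# baseline clustering variants


def agglomerative_divide(
    features: FeatureMatrix,
    inconsistency_depth: int = 2,
    inconsistency_cutoff: float = 1.15,
) -> list[Cluster]:
    """Single-linkage clustering cut by the inconsistency coefficient.

    Links whose height, standardized against the mean and standard
    deviation of link heights within ``inconsistency_depth`` levels,
    exceeds ``inconsistency_cutoff`` are cut.
    """
    X = np.asarray(features.data, dtype=float)
    if X.shape[0] < 2:
        raise ConfigurationError("need at least 2 sites")
    Z = linkage(X, method="single", metric="euclidean")
    assignment = fcluster(
        Z, t=inconsistency_cutoff, criterion="inconsistent", depth=inconsistency_depth
    )
    ids = np.asarray(features.site_ids)
    return [
        Cluster(member_ids=frozenset(ids[assignment == lab]), source="agglomerative")
        for lab in np.unique(assignment)
    ]


def subtractive_divide(
    collection: SiteCollection,
    negatives: SiteCollection,
    encoder=None,
    measure: str = "scc",
    stop: float = 0.5,
    min_cluster: int = 1,
) -> list[Cluster]:
    """Iteratively peel off the densest PWM-recoverable subset of sites.

    Each round fits a PWM on the remaining positives, learns the score
    threshold maximizing the CC/SCC measure against the negatives, removes
    the recovered true positives as one cluster and repeats while the
    measure stays above ``stop``.
    """
    from .classify import ConfusionCounts, cc, scc
    from .encode import build_pwm, score_sequence

    if len(collection) == 0 or len(negatives) == 0:
        raise ConfigurationError("positives and negatives must be non-empty")
    if encoder is None:
        encoder = build_pwm
    metric = {"cc": cc, "scc": scc}[measure]
    neg_seqs = negatives.sequences
    remaining = list(collection.sites)
    clusters: list[Cluster] = []
    while len(remaining) >= max(min_cluster, 1):
        sub = SiteCollection(remaining)
        pwm = encoder(sub)
        pos_scores = np.array([score_sequence(pwm, s) for s in sub.sequences])
        neg_scores = np.array([score_sequence(pwm, s) for s in neg_seqs])
        best_thr, best_val = None, -np.inf
        for thr in np.unique(pos_scores):
            counts = ConfusionCounts(
                TP=int((pos_scores >= thr).sum()),
                FN=int((pos_scores < thr).sum()),
                FP=int((neg_scores >= thr).sum()),
                TN=int((neg_scores < thr).sum()),
            )
            val = metric(counts)
            if val > best_val:
                best_thr, best_val = float(thr), val
        if best_val <= stop:
            if not clusters:
                warnings.warn(
                    "subtractive clustering: measure below stop at first "
                    "iteration; no clusters extracted",
                    stacklevel=2,
                )
            break
        recovered = [s for s, sc in zip(remaining, pos_scores) if sc >= best_thr]
        if not recovered:
            break
        clusters.append(
            Cluster(
                member_ids=frozenset(s.site_id for s in recovered),
                source="subtractive",
            )
        )
        remaining = [s for s, sc in zip(remaining, pos_scores) if sc < best_thr]
    return clusters


# ---------------------------------------------------------------------------
# full Divide-phase driver


def hierarchical_possibilistic(
    features: FeatureMatrix,
    c_range,
    runs_per_c: int = 5,
    seed: int = 0,
    m: float = 2.0,
    eta: float | str = "auto",
    cut: float = 0.5,
    min_size: int = 2,
    alpha_hier: float = 0.01,
    rel_tol: float = 0.05,
) -> SubmotifTree:
    """Select cluster counts, pool clusters from every optimal count and
    organize them into the submotif hierarchy."""
    chosen = select_cluster_numbers(
        features, c_range, runs_per_c=runs_per_c, seed=seed, rel_tol=rel_tol,
        m=m, eta=eta,
    )
    # the best run per chosen c is ranked at the selection bandwidth, then
    # refitted from the same seed at the extraction bandwidth so the hard
    # 0.5 membership cut keeps whole clusters
    extract_eta = "auto-max" if isinstance(eta, str) else eta
    pool: list[Cluster] = []
    seen: set[frozenset] = set()
    rng = np.random.default_rng(seed)
    for c in chosen:
        best_seed, best_xb = None, np.inf
        for _ in range(runs_per_c):
            run_seed = int(rng.integers(0, 2**31 - 1))
            part = pfcm(features, c, m=m, eta=eta, seed=run_seed)
            try:
                val = xie_beni(features, part)
            except SeparationZeroError:
                continue
            if val < best_xb:
                best_seed, best_xb = run_seed, val
        if best_seed is None:
            continue
        best_part = pfcm(features, c, m=m, eta=extract_eta, seed=best_seed)
        for cl in partition_to_clusters(
            best_part, features.site_ids, cut=cut, min_size=min_size
        ):
            if cl.member_ids not in seen:
                seen.add(cl.member_ids)
                pool.append(cl)
    return build_hierarchy(pool, features.site_ids, alpha_hier=alpha_hier)
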