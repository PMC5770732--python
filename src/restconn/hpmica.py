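"""Hierarchical partner-matched spatial ICA.

The procedure decomposes every subject's run with spatial ICA at one or
several model orders, matches components across subjects by spatial
similarity ("partner matching", first level), matches the resulting
cluster maps across model orders (second level), and keeps, for each
group of matched clusters, the single first-level cluster with the
highest Cronbach's alpha — the most internally reproducible depiction
of that network.

Spatial ICA convention: the data matrix (voxels x time) is modelled as
``S @ A.T`` with spatial sources ``S`` (voxels x N) statistically
independent over voxels and mixing time courses ``A`` (time x N).
Component maps are z-scored over the mask and sign-fixed so that each
map's skewness is non-negative (blobs point "up").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "ComponentSet",
    "ComponentCluster",
    "ClusterGroup",
    "decompose_subject",
    "match_components",
    "hierarchical_match",
    "select_reproducible",
    "cronbach_alpha",
    "cluster_onesample_map",
]


@dataclass
class ComponentSet:
    """One subject's spatial ICA decomposition at a fixed model order."""

    subject_id: str
    order: int                     # model order N (number of components)
    maps: np.ndarray               # (N, n_mask_voxels), z-scored rows
    time_courses: np.ndarray       # (t, N)
    converged: bool = True

    def __post_init__(self):
        if self.maps.shape[0] != self.time_courses.shape[1]:
            raise ValueError("maps and time_courses disagree on component count")


@dataclass
class ComponentCluster:
    """Components matched across subjects (or cluster maps across orders).

    ``members`` holds ``(owner_id, component_index, sign)`` triples; at
    most one member per owner.  ``member_maps`` are the sign-aligned
    z-scored maps in member order.
    """

    members: list[tuple[str, int, int]]
    member_maps: np.ndarray
    representative_map: np.ndarray
    mean_similarity: float
    level: str = "first"
    order: int | None = None       # model order (first level)
    alpha: float | None = None

    @property
    def owner_ids(self) -> list[str]:
        return [m[0] for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterGroup:
    """A second-level group: first-level clusters matched across orders."""

    clusters: list[ComponentCluster]     # one per contributing model order
    representative_map: np.ndarray
    mean_similarity: float

    @property
    def orders(self) -> list[int]:
        return [c.order for c in self.clusters]


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant map")
    return (v - v.mean()) / sd


def decompose_subject(run, n_components, seed=0, n_restarts=3, max_iter=1000,
                      tol=1e-5) -> ComponentSet:
    """Spatial ICA on one (standardized) run.

    Runs FastICA (logcosh negentropy contrast, PCA whitening, symmetric
    decorrelation) ``n_restarts`` times from different starting points
    and keeps the restart with the largest total negentropy proxy.
    Non-convergence in every restart is reported through the
    ``converged`` flag, never silently.
    """
    X = run.masked_timecourses()          # (voxels, t)
    n_vox, t = X.shape
    if n_components > min(n_vox, t):
        raise ValueError(f"n_components={n_components} exceeds data rank bound "
                         f"min(voxels={n_vox}, t={t})")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        rs = int(child.generate_state(1)[0] % (2 ** 31))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica = FastICA(n_components=n_components, fun="logcosh",
                          algorithm="parallel", whiten="unit-variance",
                          max_iter=max_iter, tol=tol, random_state=rs)
            sources = ica.fit_transform(X)          # (voxels, N)
        conv = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        score = _negentropy_proxy(sources)
        if best is None or (conv, score) > (best[0], best[1]):
            best = (conv, score, sources, ica.mixing_)
    conv, _, sources, mixing = best
    if not conv:
        warnings.warn(f"ICA did not converge for {run.subject_id} at order "
                      f"{n_components} in any restart")

    maps = np.empty((n_components, n_vox))
    tcs = np.empty((t, n_components))
    for k in range(n_components):
        m = _zscore(sources[:, k])
        sign = 1.0 if stats.skew(m) >= 0 else -1.0
        maps[k] = sign * m
        tcs[:, k] = sign * mixing[:, k]
    return ComponentSet(subject_id=run.subject_id, order=n_components,
                        maps=maps, time_courses=tcs, converged=conv)


def _negentropy_proxy(sources: np.ndarray) -> float:
    # J(s) ~ (E[log cosh s] - E[log cosh g])^2 for standardized s, g ~ N(0,1)
    s = (sources - sources.mean(0)) / sources.std(0)
    gauss = 0.3745672726  # E[log cosh g]
    return float(np.sum((np.mean(np.log(np.cosh(s)), axis=0) - gauss) ** 2))


# ---------------------------------------------------------------------------
# partner matching


def _greedy_match(maps: np.ndarray, owners: list[str], threshold: float):
    """Greedy reciprocal partner matching of z-scored maps.

    Seeds each cluster from the most similar remaining cross-owner pair,
    then grows it with the candidate of highest mean |r| to the current
    members, subject to: one component per owner, and every member pair
    at |r| >= threshold.  Returns a list of
    (member_indices, signs, mean_similarity) tuples ordered by
    decreasing mean within-cluster similarity.
    """
    n, n_vox = maps.shape
    corr = (maps @ maps.T) / n_vox          # Pearson r for z-scored rows
    asim = np.abs(corr)
    np.fill_diagonal(asim, -np.inf)
    same_owner = np.array([[owners[i] == owners[j] for j in range(n)]
                           for i in range(n)])
    asim[same_owner] = -np.inf

    available = np.ones(n, dtype=bool)
    clusters = []
    while True:
        sub = asim.copy()
        sub[~available, :] = -np.inf
        sub[:, ~available] = -np.inf
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < threshold:
            break
        members = [int(i), int(j)]
        signs = [1, 1 if corr[i, j] >= 0 else -1]
        used_owners = {owners[i], owners[j]}
        available[[i, j]] = False
        while True:
            best_cand, best_score, best_sign = None, -np.inf, 1
            for c in np.flatnonzero(available):
                if owners[c] in used_owners:
                    continue
                rs = asim[c, members]
                if np.min(rs) < threshold:
                    continue
                score = float(np.mean(rs))
                if score > best_score:
                    signed = float(np.sum([s * corr[c, m]
                                           for s, m in zip(signs, members)]))
                    best_cand, best_score = int(c), score
                    best_sign = 1 if signed >= 0 else -1
            if best_cand is None:
                break
            members.append(best_cand)
            signs.append(best_sign)
            used_owners.add(owners[best_cand])
            available[best_cand] = False
        pair_sims = [asim[a, b] for ai, a in enumerate(members)
                     for b in members[ai + 1:]]
        clusters.append((members, signs, float(np.mean(pair_sims))))
    clusters.sort(key=lambda c: -c[2])
    return clusters


def match_components(sets: list[ComponentSet], threshold: float = 0.4,
                     level: str = "first", order: int | None = None
                     ) -> list[ComponentCluster]:
    """First-level partner matching of components across subjects.

    Similarity is the absolute Pearson correlation between z-scored
    spatial maps; members are sign-aligned to the cluster representative
    (the z-scored mean of the aligned member maps).  Cronbach's alpha of
    each cluster is computed over voxels-as-observations and stored.
    """
    if len(sets) < 2:
        raise ValueError("partner matching needs at least 2 subjects")
    n_vox = {s.maps.shape[1] for s in sets}
    if len(n_vox) != 1:
        raise ValueError("all ComponentSets must share one mask "
                         f"(got voxel counts {sorted(n_vox)})")
    orders = {s.order for s in sets}
    if order is None and len(orders) == 1:
        order = orders.pop()

    all_maps, owners, comp_idx = [], [], []
    for s in sets:
        for k in range(s.maps.shape[0]):
            all_maps.append(s.maps[k])
            owners.append(s.subject_id)
            comp_idx.append(k)
    all_maps = np.asarray(all_maps)

    out = []
    for members, signs, msim in _greedy_match(all_maps, owners, threshold):
        mem_maps = np.array([sg * all_maps[m] for m, sg in zip(members, signs)])
        rep = _zscore(mem_maps.mean(axis=0))
        # re-align signs to the representative
        flips = np.sign(mem_maps @ rep)
        flips[flips == 0] = 1
        mem_maps = mem_maps * flips[:, None]
        triples = [(owners[m], comp_idx[m], int(sg * f))
                   for m, sg, f in zip(members, signs, flips)]
        cluster = ComponentCluster(members=triples, member_maps=mem_maps,
                                   representative_map=rep,
                                   mean_similarity=msim, level=level,
                                   order=order)
        if len(cluster) >= 2:
            cluster.alpha = cronbach_alpha(mem_maps)
        out.append(cluster)
    return out


def hierarchical_match(first_level: dict[int, list[ComponentCluster]],
                       threshold: float = 0.4,
                       min_orders: int | None = None) -> list[ClusterGroup]:
    """Second-level partner matching of cluster maps across model orders.

    ``first_level`` maps each model order to its first-level clusters.
    Cluster representative maps are matched across orders with the same
    partner-matching rule (each order playing the role of an owner).
    Groups spanning fewer than ``min_orders`` distinct orders (default:
    a majority of the supplied orders) are discarded.
    """
    if len(first_level) < 2:
        raise ValueError("hierarchical matching needs clusters from >= 2 model "
                         "orders; with a single order use match_components only")
    if min_orders is None:
        min_orders = len(first_level) // 2 + 1

    maps, owners, refs = [], [], []
    for order, clusters in sorted(first_level.items()):
        for c in clusters:
            maps.append(c.representative_map)
            owners.append(str(order))
            refs.append(c)
    maps = np.asarray(maps)

    groups = []
    matched = set()
    for members, signs, msim in _greedy_match(maps, owners, threshold):
        matched.update(members)
        clusters = [refs[m] for m in members]
        if len({c.order for c in clusters}) < min_orders:
            continue
        mem_maps = np.array([sg * maps[m] for m, sg in zip(members, signs)])
        rep = _zscore(mem_maps.mean(axis=0))
        groups.append(ClusterGroup(clusters=clusters, representative_map=rep,
                                   mean_similarity=msim))
    if min_orders <= 1:
        # unmatched cluster maps stand alone as single-order groups
        for m in range(len(refs)):
            if m not in matched:
                groups.append(ClusterGroup(clusters=[refs[m]],
                                           representative_map=maps[m],
                                           mean_similarity=1.0))
    return groups


def select_reproducible(groups: list[ClusterGroup]) -> list[ComponentCluster]:
    """Keep, per group, the first-level cluster with the highest alpha.

    Ties break toward larger membership, then lower model order.  The
    selected clusters are returned ordered by alpha, descending.
    """
    selected = []
    for g in groups:
        for c in g.clusters:
            if c.alpha is None:
                raise ValueError("every first-level cluster needs a computed alpha")
        best = max(g.clusters, key=lambda c: (c.alpha, len(c), -c.order))
        selected.append(best)
    selected.sort(key=lambda c: -c.alpha)
    return selected


# ---------------------------------------------------------------------------
# statistics


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha of ``items x observations`` data.

    ``alpha = k/(k-1) * (1 - sum_i var_i / var(sum of items))`` with
    sample variances over observations.  For matched component maps the
    items are subjects' sign-aligned maps and the observations are
    in-mask voxels, which yields one alpha per cluster.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 items and >= 2 observations")
    k = X.shape[0]
    item_vars = X.var(axis=1, ddof=1)
    total_var = X.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise ValueError("total variance of the item sum is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def cluster_onesample_map(member_maps: np.ndarray):
    """Voxelwise one-sample t over a cluster's member maps.

    Returns ``(t_values, df)`` with ``df = k - 1``.  Voxels with zero
    variance across members get a signed-infinity sentinel (0 when the
    mean is also 0).
    """
    X = np.asarray(member_maps, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("one-sample map needs >= 2 member maps")
    k = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(k))
    zero = sd == 0
    t[zero] = np.sign(mean[zero]) * np.inf
    t[zero & (mean == 0)] = 0.0
    return t, k - 1
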