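"""Markov coarse-graining of torsion-space trajectories.

Trajectories from both variants are clustered jointly by k-means in the
sine/cosine-encoded torsion feature space (Euclidean distances there respect
angular wrap-around).  The cluster count k is selected by minimizing the
Total Markov Error (TME): the summed one-step prediction error of the
cluster-level Markov chain against the observed trajectory, which trades the
coarsening loss of few clusters against the transition-estimation error of
many.  Transition probabilities use a Jeffreys (Dirichlet 1/2) prior per row,
giving posterior means c_ij = (Z_ij + 0.5) / (N_i + k/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .torsion import TrajectorySegment, encode_circular

__all__ = [
    "ClusterSolution",
    "MarkovCoarseModel",
    "MarkovErrorResult",
    "SelectKResult",
    "joint_kmeans",
    "elbow_curve",
    "silhouette_profile",
    "transition_counts",
    "transition_posterior",
    "total_markov_error",
    "select_k",
    "transition_graph",
    "proximity_graph",
]


def pool_trajectories(trajectories: list[TrajectorySegment]):
    """Stack encoded frames of all trajectories; frames keep trajectory order."""
    mats, traj_ids, variants = [], [], []
    for tid, traj in enumerate(trajectories):
        enc = encode_circular(traj.conformations)
        mats.append(enc.matrix)
        traj_ids.append(np.full(enc.n_rows, tid))
        variants.append(enc.variants)
    return (np.vstack(mats), np.concatenate(traj_ids),
            np.concatenate(variants))


@dataclass
class ClusterSolution:
    """A joint k-means coarsening of pooled trajectory frames.

    Assignments are 1-based cluster ids; `features` retains the encoded
    frames (needed for member pools, medoids, and TME evaluation).
    """

    k: int
    centers: np.ndarray
    assignments: np.ndarray
    features: np.ndarray
    traj_ids: np.ndarray
    variants: np.ndarray
    inertia: float

    @property
    def n_frames(self) -> int:
        return self.assignments.shape[0]

    def members(self, cluster: int, variant=None) -> np.ndarray:
        """Frame indices belonging to a (1-based) cluster."""
        mask = self.assignments == cluster
        if variant is not None:
            mask &= self.variants == variant
        return np.nonzero(mask)[0]

    def frames_of(self, traj_id: int):
        mask = self.traj_ids == traj_id
        return self.features[mask], self.assignments[mask]

    def mean_center_distance(self) -> float:
        d = np.linalg.norm(self.features - self.centers[self.assignments - 1],
                           axis=1)
        return float(d.mean())

    def medoid_frames(self) -> np.ndarray:
        """Global frame index nearest each cluster center."""
        out = np.empty(self.k, dtype=int)
        for c in range(1, self.k + 1):
            idx = self.members(c)
            d = np.linalg.norm(self.features[idx] - self.centers[c - 1], axis=1)
            out[c - 1] = idx[np.argmin(d)]
        return out

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trajectory": self.traj_ids,
            "variant": self.variants,
            "cluster": self.assignments,
        })


def joint_kmeans(trajectories: list[TrajectorySegment], k: int,
                 seed: int = 0, n_init: int = 10) -> ClusterSolution:
    """Best-of-`n_init` k-means over the pooled encoded frames of all
    trajectories (shared coarsening of the variants' common space)."""
    X, traj_ids, variants = pool_trajectories(trajectories)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds frame count {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return ClusterSolution(
        k=k, centers=km.cluster_centers_, assignments=km.labels_ + 1,
        features=X, traj_ids=traj_ids, variants=variants,
        inertia=float(km.inertia_))


def elbow_curve(trajectories: list[TrajectorySegment],
                k_range=range(2, 17), reps: int = 20,
                seed: int = 0, n_init: int = 10) -> pd.DataFrame:
    """Mean distance-to-center as a function of k, averaged over `reps`
    independently seeded clusterings per k."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        vals = [joint_kmeans(trajectories, k,
                             seed=int(rng.integers(2 ** 31)),
                             n_init=n_init).mean_center_distance()
                for _ in range(reps)]
        rows.append((k, float(np.mean(vals)), float(np.std(vals, ddof=1))
                     if reps > 1 else 0.0))
    return pd.DataFrame(rows, columns=["k", "mean_distance", "sd"])


def _silhouette_values(X: np.ndarray, labels: np.ndarray,
                       sample_idx: np.ndarray) -> np.ndarray:
    """s(i) = (b(i) - a(i)) / max(a(i), b(i)) for the sampled points,
    computed against the full data set.  Singletons get s = 0."""
    ks = np.unique(labels)
    D = cdist(X[sample_idx], X)
    sums = np.stack([D[:, labels == c].sum(axis=1) for c in ks], axis=1)
    counts = np.array([(labels == c).sum() for c in ks])
    own_col = np.searchsorted(ks, labels[sample_idx])
    s = np.zeros(sample_idx.size)
    for row in range(sample_idx.size):
        c = own_col[row]
        n_own = counts[c]
        if n_own <= 1:
            continue  # singleton convention: s = 0
        a = sums[row, c] / (n_own - 1)  # self-distance is 0 and excluded
        other = [sums[row, cc] / counts[cc] for cc in range(len(ks)) if cc != c]
        b = min(other)
        denom = max(a, b)
        s[row] = 0.0 if denom == 0 else (b - a) / denom
    return s


def silhouette_profile(solution: ClusterSolution, sample_size: int = 5000,
                       reps: int = 10, seed: int = 0) -> float:
    """Mean silhouette width estimated from `reps` subsamples of
    `sample_size` points (sampled values are exact against the full data)."""
    if solution.k < 2:
        raise ValueError("silhouette requires k >= 2")
    n = solution.n_frames
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        idx = (np.arange(n) if sample_size >= n
               else rng.choice(n, size=sample_size, replace=False))
        vals.append(_silhouette_values(solution.features,
                                       solution.assignments, idx).mean())
    return float(np.mean(vals))


@dataclass
class MarkovCoarseModel:
    """Transition-count matrix Z with Jeffreys posterior-mean transitions."""

    Z: np.ndarray
    C: np.ndarray | None = None

    def __post_init__(self):
        self.Z = np.asarray(self.Z)
        if np.any(self.Z < 0):
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> int:
        return self.Z.shape[0]

    @property
    def row_totals(self) -> np.ndarray:
        return self.Z.sum(axis=1)


def transition_counts(solution: ClusterSolution,
                      variant=None) -> MarkovCoarseModel:
    """Directed transition counts Z_ij over consecutive frame pairs.

    Counting is per trajectory (never across trajectory boundaries); with
    `variant` given, only that variant's trajectories contribute.
    """
    k = solution.k
    Z = np.zeros((k, k), dtype=np.int64)
    for tid in np.unique(solution.traj_ids):
        mask = solution.traj_ids == tid
        if variant is not None and solution.variants[mask][0] != variant:
            continue
        a = solution.assignments[mask] - 1
        np.add.at(Z, (a[:-1], a[1:]), 1)
    return MarkovCoarseModel(Z)


def transition_posterior(model: MarkovCoarseModel,
                         k: int | None = None) -> np.ndarray:
    """Jeffreys posterior-mean transition matrix:
    c_ij = (Z_ij + 0.5) / (N_i + k/2).  Rows sum to 1 by the identity
    sum_j (Z_ij + 0.5) = N_i + k/2; an unobserved row is uniform."""
    Z = model.Z
    if k is None:
        k = Z.shape[0]
    elif k != Z.shape[0]:
        raise ValueError("k must equal the count-matrix dimension")
    N = Z.sum(axis=1, keepdims=True)
    C = (Z + 0.5) / (N + k / 2.0)
    model.C = C
    return C


@dataclass
class MarkovErrorResult:
    """Total Markov error of one trajectory under a coarse model."""

    total: float
    trace: np.ndarray
    mode: str
    seed: int | None = None

    def __post_init__(self):
        assert self.total >= 0


def _member_pools(solution: ClusterSolution, variant=None):
    pools = []
    for c in range(1, solution.k + 1):
        pools.append(solution.members(c, variant))
    return pools


def total_markov_error(solution: ClusterSolution, traj_id: int,
                       C: np.ndarray, mode: str = "expected",
                       seed: int = 0,
                       member_pool: str = "pooled") -> MarkovErrorResult:
    """One-step prediction error of the coarse Markov model, summed along a
    trajectory.

    At each consecutive frame pair, the model predicts the next cluster from
    the current one and represents the prediction by a member conformation of
    the predicted cluster.  `sampled` mode draws cluster and member at
    random; `expected` mode accumulates the exact expectation
    sum_j c_ij * meanDist(next frame, members of j).  The first frame seeds
    the walk and accrues no error.
    """
    if mode not in ("sampled", "expected"):
        raise ValueError("mode must be 'sampled' or 'expected'")
    feats, assign = solution.frames_of(traj_id)
    T = assign.shape[0]
    if T < 2:
        return MarkovErrorResult(0.0, np.zeros(0), mode, seed)
    variant = None
    if member_pool == "per_variant":
        variant = solution.variants[solution.traj_ids == traj_id][0]
    pools = _member_pools(solution, variant)
    reachable = np.nonzero(C[np.unique(assign) - 1].max(axis=0) > 0)[0]
    for j in reachable:
        if pools[j].size == 0:
            raise ValueError(f"cluster {j + 1} is reachable but has no "
                             f"members in the {member_pool} pool")
    if mode == "expected":
        D = cdist(feats[1:], solution.features)  # (T-1, n_frames)
        M = np.stack([D[:, pools[j]].mean(axis=1) for j in range(solution.k)],
                     axis=1)
        trace = np.einsum("tj,tj->t", M, C[assign[:-1] - 1])
        return MarkovErrorResult(float(trace.sum()), trace, mode, None)
    rng = np.random.default_rng(seed)
    trace = np.empty(T - 1)
    for t in range(T - 1):
        j = rng.choice(solution.k, p=C[assign[t] - 1])
        m = rng.choice(pools[j])
        trace[t] = np.linalg.norm(feats[t + 1] - solution.features[m])
    return MarkovErrorResult(float(trace.sum()), trace, mode, seed)


@dataclass
class SelectKResult:
    selected_k: int
    table: pd.DataFrame
    best_solution: ClusterSolution
    best_models: dict  # variant -> (MarkovCoarseModel, C)


def _tme_of_solution(solution: ClusterSolution, mode: str, seed: int,
                     member_pool: str = "pooled") -> float:
    """Summed TME over all trajectories, each under its own variant's
    posterior transition matrix estimated from the joint solution."""
    total = 0.0
    cs = {}
    for v in np.unique(solution.variants):
        cs[v] = transition_posterior(transition_counts(solution, variant=v))
    for tid in np.unique(solution.traj_ids):
        v = solution.variants[solution.traj_ids == tid][0]
        total += total_markov_error(solution, int(tid), cs[v], mode=mode,
                                    seed=seed + int(tid),
                                    member_pool=member_pool).total
    return total


def select_k(trajectories: list[TrajectorySegment],
             k_range=range(2, 17), reps: int = 20, seed: int = 0,
             mode: str = "expected", n_init: int = 10,
             member_pool: str = "pooled") -> SelectKResult:
    """Choose the cluster count minimizing the mean summed TME.

    For each k, `reps` independently seeded clusterings (each the best of
    `n_init` k-means restarts) are evaluated; the summed TME over all
    trajectories (all variants) is averaged.  Returns the
    argmin k and, within it, the minimum-TME solution with its per-variant
    transition models.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    rng = np.random.default_rng(seed)
    seeds = {k: [int(rng.integers(2 ** 31)) for _ in range(reps)]
             for k in k_range}
    rows = []
    tmes_by_k = {}
    for k in k_range:
        tmes = []
        for s in seeds[k]:
            sol = joint_kmeans(trajectories, k, seed=s, n_init=n_init)
            tmes.append(_tme_of_solution(sol, mode, seed=s,
                                         member_pool=member_pool))
        tmes_by_k[k] = tmes
        rows.append((k, float(np.mean(tmes)), float(np.min(tmes))))
    table = pd.DataFrame(rows, columns=["k", "mean_tme", "min_tme"])
    sel_k = int(table.loc[table["mean_tme"].idxmin(), "k"])
    # re-materialize the minimum-TME solution within the selected k
    best_seed = seeds[sel_k][int(np.argmin(tmes_by_k[sel_k]))]
    best_sol = joint_kmeans(trajectories, sel_k, seed=best_seed,
                            n_init=n_init)
    models = {}
    for v in np.unique(best_sol.variants):
        m = transition_counts(best_sol, variant=v)
        models[v] = (m, transition_posterior(m))
    return SelectKResult(sel_k, table, best_sol, models)


def transition_graph(model: MarkovCoarseModel, solution: ClusterSolution,
                     variant, color_variant=None):
    """Annotated directed transition graph for one variant.

    Vertices carry the variant's cluster populations, a color scalar in
    [0, 1] (fraction of frames from `color_variant` in the pooled cluster;
    defaults to the lexicographically last variant) and the medoid frame id;
    edges carry observed transition counts.
    """
    import networkx as nx

    if color_variant is None:
        color_variant = sorted(np.unique(solution.variants))[-1]
    g = nx.DiGraph()
    medoids = solution.medoid_frames()
    for c in range(1, solution.k + 1):
        pooled = solution.members(c)
        pop = solution.members(c, variant).size
        frac = (float((solution.variants[pooled] == color_variant).mean())
                if pooled.size else 0.0)
        g.add_node(c, population=int(pop), variant_fraction=frac,
                   medoid_frame=int(medoids[c - 1]))
    for i in range(solution.k):
        for j in range(solution.k):
            if model.Z[i, j] > 0:
                g.add_edge(i + 1, j + 1, count=int(model.Z[i, j]))
    return g


def proximity_graph(solution: ClusterSolution,
                    sigmoid_midpoint: float | None = None,
                    sigmoid_slope: float | None = None):
    """Complete weighted graph of pairwise cluster-center distances.

    Each edge carries the Euclidean center distance and a grayscale value
    sigmoid(distance) in (0, 1), monotone increasing (closer pairs darker).
    Defaults: midpoint = median pairwise distance; slope = 1 / SD of the
    pairwise distances, so the grayscale distribution tracks the shape of
    the distance distribution through the quasi-linear sigmoid midrange.
    """
    import networkx as nx

    k = solution.k
    if k < 2:
        raise ValueError("proximity graph requires k >= 2")
    D = cdist(solution.centers, solution.centers)
    iu, ju = np.triu_indices(k, 1)
    dists = D[iu, ju]
    if sigmoid_midpoint is None:
        sigmoid_midpoint = float(np.median(dists))
    if sigmoid_slope is None:
        sd = float(np.std(dists))
        sigmoid_slope = 1.0 / sd if sd > 0 else 1.0
    g = nx.Graph()
    g.add_nodes_from(range(1, k + 1))
    for i, j, d in zip(iu, ju, dists):
        gray = 1.0 / (1.0 + np.exp(-sigmoid_slope * (d - sigmoid_midpoint)))
        g.add_edge(int(i + 1), int(j + 1), distance=float(d),
                   grayscale=float(gray))
    return g
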