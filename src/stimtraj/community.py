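"""Subject-similarity graph and Louvain community detection over treatment profiles.

Profiles mix years, mg and dimensionless fractions, so each feature is
z-scored first. Similarity is a Gaussian kernel on the Euclidean distance in
z-space, w_ij = exp(-||z_i - z_j||^2 / (2 sigma^2)) with sigma set to the
median pairwise distance — a parameter-light, deterministic construction; the
graph is complete with no self-loops.

Modularity is the weighted Newman-Girvan form
    Q = (1/2m) sum_ij [w_ij - k_i k_j / 2m] delta(c_i, c_j),
and the optimizer is the classic two-phase Louvain algorithm (greedy local
moving in a seeded random node order, then community aggregation, repeated to
a fixed point), restarted from several seeds and keeping the best partition.
Stimulant-naive subjects never enter the graph; they are appended afterwards
as their own subgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DataError, DegenerateDataError
from .smoothing import FEATURE_NAMES, TreatmentProfile, profiles_to_matrix

GAIN_TOL = 1e-10  # minimal modularity gain for a local move
PHASE_TOL = 1e-8  # minimal gain for another aggregation phase

#: Canonical subgroup names, in the order used for reporting.
SUBGROUP_NAMES = ("early_and_intense", "early_and_moderate", "late_and_moderate")
NAIVE_LABEL = "stimulant_naive"


@dataclass
class SimilarityGraph:
    node_ids: list[str]
    weights: np.ndarray  # symmetric, non-negative, zero diagonal

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def total_weight(self) -> float:
        """m = sum of edge weights (each undirected edge counted once)."""
        return float(self.weights.sum()) / 2.0


@dataclass
class Partition:
    labels: dict[str, int]  # node id -> community index
    k: int
    q: float


@dataclass
class StabilityReport:
    b: int
    ks: np.ndarray  # per-replicate community count
    qs: np.ndarray  # per-replicate modularity
    modal_k: int
    stability_fraction: float  # fraction of replicates at the modal k
    mean_q: float
    sd_q: float
    mean_ari: float | None = None  # vs the full-sample partition, when supplied
    aris: np.ndarray | None = field(default=None, repr=False)


def standardize(profiles) -> np.ndarray:
    """Z-score the (subjects x 6) feature matrix, population SD per column."""
    X = profiles_to_matrix(profiles) if not isinstance(profiles, np.ndarray) else profiles
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("standardize needs at least 2 subjects")
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i) for i in zero]
        raise DegenerateDataError(f"zero-variance feature(s): {', '.join(names)}")
    return (X - X.mean(axis=0)) / sd


def build_graph(z: np.ndarray, node_ids: list[str] | None = None) -> SimilarityGraph:
    """Complete Gaussian-kernel graph on z-scored profiles."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] < 2:
        raise DataError("graph needs at least 2 subjects")
    d = pdist(z)
    sigma = float(np.median(d))
    if sigma == 0:
        raise DegenerateDataError("all pairwise distances are zero; degenerate cohort")
    W = squareform(np.exp(-(d**2) / (2 * sigma**2)))
    np.fill_diagonal(W, 0.0)
    if node_ids is None:
        node_ids = [str(i) for i in range(z.shape[0])]
    return SimilarityGraph(node_ids=list(node_ids), weights=W)


def recompute_modularity(graph: SimilarityGraph, labels: dict[str, int]) -> float:
    """Weighted Newman-Girvan modularity of a labeling."""
    missing = [nid for nid in graph.node_ids if nid not in labels]
    if missing:
        raise DataError(f"unlabeled node(s): {missing[:5]}")
    comm = np.array([labels[nid] for nid in graph.node_ids])
    return _modularity_from_array(graph.weights, comm)


def _modularity_from_array(W: np.ndarray, comm: np.ndarray) -> float:
    two_m = W.sum()
    if two_m <= 0:
        raise DegenerateDataError("graph has no edge weight")
    deg = W.sum(axis=1)
    q = 0.0
    for c in np.unique(comm):
        mask = comm == c
        q += W[np.ix_(mask, mask)].sum() / two_m - (deg[mask].sum() / two_m) ** 2
    return float(q)


def _local_moving(
    W: np.ndarray, deg: np.ndarray, two_m: float, rng, init: np.ndarray | None = None
) -> np.ndarray:
    """Phase 1: greedy modularity-gain moves in a seeded random node order.

    ``W`` may carry self-loops on the diagonal (aggregated graphs); the
    diagonal entry holds the full internal weight (both directions) and is
    included in ``deg``. Self-loops never affect move gains. ``init`` seeds
    the starting assignment (default: singletons).
    """
    n = W.shape[0]
    comm = np.arange(n) if init is None else init.copy()
    comm_tot = deg.copy() if init is None else np.bincount(comm, weights=deg, minlength=n)
    order = rng.permutation(n)
    improved = True
    while improved:
        improved = False
        for i in order:
            ci = comm[i]
            # weight from i to each community, excluding the self-loop
            w_to = np.bincount(comm, weights=W[i], minlength=n)
            w_to[comm[i]] -= W[i, i]
            comm_tot[ci] -= deg[i]
            # gain of joining community c (relative to staying isolated):
            # dQ = w_to[c]/m - deg_i * comm_tot[c] / (2 m^2)
            gains = w_to / (two_m / 2) - deg[i] * comm_tot / (2 * (two_m / 2) ** 2)
            best_c = ci
            best_gain = gains[ci]
            candidates = np.flatnonzero(w_to > 0)
            for c in candidates:
                if gains[c] > best_gain + GAIN_TOL:
                    best_gain = gains[c]
                    best_c = c
            comm_tot[best_c] += deg[i]
            if best_c != ci:
                comm[i] = best_c
                improved = True
    return comm


def _aggregate(W: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Phase 2: collapse communities into super-nodes with self-loops."""
    uniq, dense = np.unique(comm, return_inverse=True)
    k = uniq.size
    n = W.shape[0]
    M = np.zeros((n, k))
    M[np.arange(n), dense] = 1.0
    Wagg = M.T @ W @ M  # diagonal = full internal weight (both directions)
    return Wagg, dense


def louvain(
    graph: SimilarityGraph, seed: int, resolution: float = 1.0, restarts: int = 20
) -> Partition:
    """Two-phase Louvain modularity optimization, best of ``restarts`` seeded runs."""
    if resolution != 1.0:
        raise NotImplementedError("only classic modularity (resolution 1) is supported")
    W0 = graph.weights
    two_m = W0.sum()
    if two_m <= 0:
        raise DegenerateDataError("graph has no edge weight")
    ss = np.random.SeedSequence(seed)
    best_labels, best_q = None, -np.inf
    for r, child in enumerate(ss.spawn(restarts)):
        rng = np.random.default_rng(child)
        W = W0.copy()
        assign = np.arange(graph.n)  # original node -> current super-node
        q_prev = _modularity_from_array(W0, assign)
        # restart 0 is the classic singleton start; later restarts begin the
        # first level from a seeded random partition to escape greedy basins
        init = rng.integers(0, graph.n, size=graph.n) if r > 0 else None
        first_level = True
        while True:
            deg = W.sum(axis=1)
            comm = _local_moving(W, deg, two_m, rng, init=init if first_level else None)
            first_level = False
            W, dense = _aggregate(W, comm)
            assign = dense[comm[assign]]
            q_now = _modularity_from_array(W0, assign)
            if q_now - q_prev < PHASE_TOL:
                break
            q_prev = q_now
        if q_now > best_q:
            best_q, best_labels = q_now, assign.copy()
    # canonicalize community indices by order of first appearance
    _, canonical = np.unique(best_labels, return_inverse=True)
    first_seen = {}
    relabel = np.empty_like(canonical)
    nxt = 0
    for i, c in enumerate(canonical):
        if c not in first_seen:
            first_seen[c] = nxt
            nxt += 1
        relabel[i] = first_seen[c]
    labels = {nid: int(relabel[i]) for i, nid in enumerate(graph.node_ids)}
    q = recompute_modularity(graph, labels)
    return Partition(labels=labels, k=int(relabel.max()) + 1, q=q)


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise DataError("labelings must cover the same items")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    C = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(C, (ai, bi), 1)
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(C).sum()
    sum_a = comb(C.sum(axis=1)).sum()
    sum_b = comb(C.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def bootstrap_stability(
    profiles: list[TreatmentProfile],
    b: int = 1000,
    seed: int = 0,
    reference: Partition | None = None,
) -> StabilityReport:
    """Non-parametric bootstrap of the community solution.

    Each replicate resamples treated subjects with replacement (duplicates
    kept as distinct graph nodes), re-standardizes the features, rebuilds the
    kernel graph (sigma recomputed), and runs Louvain with a single restart
    and a replicate-specific seed. Stability is the fraction of replicates
    whose community count equals the modal count; when the full-sample
    partition is supplied, the mean adjusted Rand index of each replicate
    against it (on the resampled subjects) is reported as well.
    """
    if b < 1:
        raise DataError("bootstrap needs B >= 1 replicates")
    n = len(profiles)
    X = profiles_to_matrix(profiles)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rep_seeds = ss.generate_state(b)
    ks = np.empty(b, dtype=int)
    qs = np.empty(b)
    aris = np.empty(b) if reference is not None else None
    ref_arr = (
        np.array([reference.labels[p.subject_id] for p in profiles])
        if reference is not None
        else None
    )
    for rep in range(b):
        idx = rng.integers(0, n, size=n)
        z = standardize(X[idx])
        g = build_graph(z, node_ids=[str(i) for i in range(n)])
        part = louvain(g, seed=int(rep_seeds[rep] % (2**31 - 1)), restarts=1)
        ks[rep] = part.k
        qs[rep] = part.q
        if aris is not None:
            rep_labels = np.array([part.labels[str(i)] for i in range(n)])
            aris[rep] = adjusted_rand_index(rep_labels, ref_arr[idx])
    vals, counts = np.unique(ks, return_counts=True)
    modal_k = int(vals[np.argmax(counts)])
    return StabilityReport(
        b=b,
        ks=ks,
        qs=qs,
        modal_k=modal_k,
        stability_fraction=float(np.mean(ks == modal_k)),
        mean_q=float(qs.mean()),
        sd_q=float(qs.std(ddof=1)) if b > 1 else 0.0,
        mean_ari=float(aris.mean()) if aris is not None else None,
        aris=aris,
    )


def label_subgroups(
    partition: Partition,
    profiles: list[TreatmentProfile],
    naive_ids: list[str],
) -> list[tuple[str, int, str]]:
    """Name communities by their feature means and append the naive subgroup.

    With exactly three communities: the one with both the earliest mean start
    age and the highest mean maximum dose is ``early_and_intense``; of the
    remaining two, the earlier mean start age is ``early_and_moderate`` and
    the later is ``late_and_moderate``. Any other community count — or a
    naming ambiguity — yields neutral labels C1..Ck ordered by size.

    Returns (subject_id, community, label) rows; naive subjects carry
    community -1 and the ``stimulant_naive`` label.
    """
    by_comm: dict[int, list[TreatmentProfile]] = {}
    for p in profiles:
        by_comm.setdefault(partition.labels[p.subject_id], []).append(p)

    names: dict[int, str] = {}
    if len(by_comm) == 3:
        start = {c: np.mean([p.start_age for p in ps]) for c, ps in by_comm.items()}
        maxd = {c: np.mean([p.max_dose for p in ps]) for c, ps in by_comm.items()}
        c_start = min(start, key=start.get)
        c_dose = max(maxd, key=maxd.get)
        n_min_start = sum(1 for v in start.values() if v == start[c_start])
        n_max_dose = sum(1 for v in maxd.values() if v == maxd[c_dose])
        if c_start == c_dose and n_min_start == 1 and n_max_dose == 1:
            names[c_start] = "early_and_intense"
            rest = sorted((c for c in by_comm if c != c_start), key=start.get)
            names[rest[0]] = "early_and_moderate"
            names[rest[1]] = "late_and_moderate"
        else:
            warnings.warn(
                "subgroup naming ambiguous (earliest-start and highest-dose "
                "communities differ or are tied); using neutral labels",
                stacklevel=2,
            )
    if not names:
        by_size = sorted(by_comm, key=lambda c: (-len(by_comm[c]), c))
        names = {c: f"C{i + 1}" for i, c in enumerate(by_size)}

    rows = [(p.subject_id, partition.labels[p.subject_id], names[partition.labels[p.subject_id]])
            for p in profiles]
    seen = {r[0] for r in rows}
    for nid in naive_ids:
        if nid not in seen:
            rows.append((nid, -1, NAIVE_LABEL))
            seen.add(nid)
    return rows


def write_partition(rows: list[tuple[str, int, str]], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["subject_id", "community", "label"])
        w.writerows(rows)


def read_partition(path) -> list[tuple[str, int, str]]:
    import csv

    from .errors import FormatError

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != ["subject_id", "community", "label"]:
        raise FormatError(f"{path}: expected header subject_id,community,label")
    return [(r[0], int(r[1]), r[2]) for r in rows[1:]]
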