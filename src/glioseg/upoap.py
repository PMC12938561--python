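"""Stage 2 core: patch-wise optimized affinity propagation with hierarchy.

Voxels inside the whole-tumor mask are described by per-modality intensity
feature vectors (z-scored over the masked region) and grouped by an
exemplar-based message-passing scheme:

* similarity is negative scale-normalized Manhattan distance,
  ``s(i, k) = -sum_b |A_i^b - A_k^b| / sigma_b``, maximal (0) for identical
  points;
* the self-similarity (preference) controls how readily a point becomes an
  exemplar — either the median pairwise similarity (shared, default) or
  per-point row means;
* responsibilities and availabilities are exchanged iteratively and
  stabilized by a moving average with a four-iteration effective memory
  instead of a separate damping factor;
* exemplars are the points whose combined smoothed message evidence
  (responsibility plus availability) peaks at themselves.

A hierarchical pass re-clusters the pooled level-1 exemplars (up to three
levels) to merge redundant clusters across patches, and an intra/inter
separation score selects the best level. Everything is deterministic:
there is no random initialization and ties resolve to the lowest index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from glioseg.volume_io import BinaryMask, MultiModalVolume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class APConfig:
    """Clustering configuration.

    ``patch_size``/``overlap`` control the tiling of the masked bounding
    box (5^3 windows at 50% overlap by default, i.e. stride 2).
    Message passing stops once the exemplar set is unchanged for
    ``convergence_window`` consecutive iterations or after
    ``max_iterations``. ``max_recluster_size`` bounds the problem size of
    one hierarchical re-clustering run; larger exemplar pools are merged
    in deterministic chunks, which consumes one hierarchy level.
    """

    patch_size: int = 5
    overlap: float = 0.5
    max_iterations: int = 200
    convergence_window: int = 15
    max_hierarchy_levels: int = 3
    preference_mode: str = "median_similarity"  # or "row_mean"
    smoothing_window: int = 4
    max_recluster_size: int = 1000

    def __post_init__(self) -> None:
        if self.preference_mode not in ("median_similarity", "row_mean"):
            raise ValueError(f"unknown preference mode: {self.preference_mode}")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def stride(self) -> int:
        return max(1, int(self.patch_size * (1.0 - self.overlap)))


@dataclass
class PatchFeatureSet:
    """Masked voxels of one tiling window with their feature vectors.

    ``voxel_indices`` index into the global masked-voxel arrays;
    ``features`` holds one row per voxel (modalities ordered T1, T1ce,
    T2, FLAIR, absent modalities omitted). ``sigmas`` is the per-modality
    scale of the whole masked region (ones for z-scored features).
    """

    voxel_indices: np.ndarray
    coords: np.ndarray
    features: np.ndarray
    patch_id: int = 0
    sigmas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.int64)
        self.features = np.asarray(self.features, dtype=np.float64)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")

    def __len__(self) -> int:
        return int(self.features.shape[0])


@dataclass
class Partition:
    """Cluster assignment plus exemplar indices at one hierarchy level.

    ``exemplars[c]`` is the index (into the point set the assignment
    covers) of cluster ``c``'s exemplar; every exemplar is assigned to
    its own cluster.
    """

    assignment: np.ndarray
    exemplars: np.ndarray
    level: int = 1

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        self.exemplars = np.asarray(self.exemplars, dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return int(self.exemplars.shape[0])


@dataclass
class MessageState:
    """Responsibility/availability messages with a 4-deep smoothing buffer.

    ``r``/``a`` hold the raw updates of the latest iteration; ``r_hat``/
    ``a_hat`` are the propagated smoothed messages — a moving average with
    an effective memory of the last ``smoothing_window`` iterations
    (messages before the first iteration count as zero). ``history`` is a
    ring buffer of the most recent (at most four) raw snapshots, kept for
    inspection.
    """

    r: np.ndarray
    a: np.ndarray
    r_hat: np.ndarray
    a_hat: np.ndarray
    history: List[Tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    iteration: int = 0

    @classmethod
    def zeros(cls, n: int) -> "MessageState":
        z = np.zeros((n, n))
        return cls(r=z.copy(), a=z.copy(), r_hat=z.copy(), a_hat=z.copy())


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def masked_features(volume: MultiModalVolume, mask: BinaryMask,
                    zscore: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel multi-modal feature matrix over the mask.

    Returns ``(coords, features, sigmas)`` where coords is (N, 3),
    features is (N, B) with modalities in canonical order, and sigmas is
    the per-modality scale after the optional z-scoring (ones when
    z-scored).
    """
    if mask.data.shape != volume.shape:
        raise ValueError("mask shape differs from volume shape")
    if not mask.data.any():
        raise ValueError("empty mask")
    coords = np.argwhere(mask.data)
    feats = np.column_stack([volume.data[m][mask.data] for m in volume.modalities])
    if zscore:
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        degenerate = sd < 1e-12
        if degenerate.any():
            log.warning("constant modality over mask: left unscaled (indices %s)",
                        np.flatnonzero(degenerate).tolist())
        sd = np.where(degenerate, 1.0, sd)
        feats = (feats - mu) / sd
        sigmas = np.ones(feats.shape[1])
    else:
        sigmas = feats.std(axis=0)
    return coords, feats, sigmas


def extract_patches(volume: MultiModalVolume, mask: BinaryMask,
                    config: APConfig = APConfig()) -> List[PatchFeatureSet]:
    """Tile the mask's bounding box into overlapping feature patches.

    Windows of ``patch_size``^3 are placed at the configured stride
    (an extra final window per axis guarantees full coverage of the
    bounding box); a patch is emitted iff it contains at least one masked
    voxel. Features are z-scored per modality over all masked voxels.
    """
    coords, feats, sigmas = masked_features(volume, mask, zscore=True)
    index_grid = np.full(volume.shape, -1, dtype=np.int64)
    index_grid[tuple(coords.T)] = np.arange(coords.shape[0])

    lo = coords.min(axis=0)
    hi = coords.max(axis=0)  # inclusive
    p, stride = config.patch_size, config.stride

    def axis_origins(a: int) -> list[int]:
        extent = int(hi[a] - lo[a] + 1)
        last = max(0, extent - p)
        origins = list(range(0, last + 1, stride))
        if origins[-1] != last:
            origins.append(last)
        return [int(lo[a]) + o for o in origins]

    patches: List[PatchFeatureSet] = []
    pid = 0
    for ox in axis_origins(0):
        for oy in axis_origins(1):
            for oz in axis_origins(2):
                window = index_grid[ox:ox + p, oy:oy + p, oz:oz + p]
                idx = window[window >= 0]
                if idx.size == 0:
                    continue
                idx = np.sort(idx)
                patches.append(PatchFeatureSet(
                    voxel_indices=idx, coords=coords[idx],
                    features=feats[idx], patch_id=pid, sigmas=sigmas,
                ))
                pid += 1
    return patches


# ---------------------------------------------------------------------------
# similarity / preferences
# ---------------------------------------------------------------------------

def build_similarity(features_or_patch, sigmas: np.ndarray | None = None) -> np.ndarray:
    """Similarity matrix: negative sigma-normalized Manhattan distance.

    ``s(i, k) = -sum_b |A_i^b - A_k^b| / sigma_b``; symmetric, zero on the
    diagonal (the preference is written there later). A modality with zero
    scale contributes nothing and is reported via a logged diagnostic.
    """
    if isinstance(features_or_patch, PatchFeatureSet):
        feats = features_or_patch.features
        if sigmas is None:
            sigmas = features_or_patch.sigmas
    else:
        feats = np.asarray(features_or_patch, dtype=np.float64)
    if feats.ndim != 2 or feats.shape[0] < 1:
        raise ValueError("features must be a nonempty (L, B) matrix")
    if sigmas is None:
        sigmas = feats.std(axis=0)
    sigmas = np.asarray(sigmas, dtype=np.float64)
    usable = sigmas > 0
    if not usable.all():
        log.warning("dropping %d zero-scale modality term(s) from the similarity",
                    int((~usable).sum()))
    if not usable.any():
        return np.zeros((feats.shape[0], feats.shape[0]))
    scaled = feats[:, usable] / sigmas[usable]
    return -cdist(scaled, scaled, metric="cityblock")


def pairwise_distance(x: np.ndarray, y: np.ndarray,
                      sigmas: np.ndarray | None = None) -> np.ndarray:
    """Sigma-normalized Manhattan distances between two feature sets."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if sigmas is None:
        sigmas = np.ones(x.shape[1])
    sigmas = np.asarray(sigmas, dtype=np.float64)
    usable = sigmas > 0
    if not usable.any():
        return np.zeros((x.shape[0], y.shape[0]))
    return cdist(x[:, usable] / sigmas[usable], y[:, usable] / sigmas[usable],
                 metric="cityblock")


def compute_preferences(S: np.ndarray, mode: str = "median_similarity") -> np.ndarray:
    """Per-point preference vector to be written to the diagonal of S.

    ``row_mean`` averages each row of S (diagonal included, as
    initialized to 0); ``median_similarity`` uses one shared value, the
    median off-diagonal similarity.
    """
    S = np.asarray(S)
    L = S.shape[0]
    if L == 0:
        raise ValueError("empty similarity matrix")
    if mode == "row_mean":
        return S.mean(axis=1)
    if mode == "median_similarity":
        if L == 1:
            return np.zeros(1)
        off = S[~np.eye(L, dtype=bool)]
        return np.full(L, np.median(off))
    raise ValueError(f"unknown preference mode: {mode}")


# ---------------------------------------------------------------------------
# message passing
# ---------------------------------------------------------------------------

def _availability(r: np.ndarray) -> np.ndarray:
    # a(i,k) = min(0, r(k,k) + sum_{k' not in {i,k}} max(0, r(k',k))), i != k
    # a(k,k) =            sum_{k' != k} max(0, r(k',k))
    # the support sum excludes the recipient's own responsibility: counting
    # a point's own vote toward the availability it receives lets tiny
    # candidate sets self-certify and collapse into one cluster
    rp = np.maximum(r, 0.0)
    np.fill_diagonal(rp, 0.0)
    support = rp.sum(axis=0)
    a = np.minimum(0.0, np.diag(r)[None, :] + support[None, :] - rp)
    np.fill_diagonal(a, support)
    return a


def ap_step(state: MessageState, S: np.ndarray, preferences: np.ndarray,
            smoothing_window: int = 4) -> MessageState:
    """One responsibility/availability update plus moving-average smoothing.

    Raw responsibilities are computed from the smoothed availabilities of
    the previous iterations (the candidate's own preference stands in for
    its self-similarity); raw availabilities from the freshly smoothed
    responsibilities. The smoothed messages are exponential moving
    averages with an effective memory of ``smoothing_window`` iterations
    (weight ``(w-1)/w`` on the running value, ``1/w`` on the fresh raw
    update, zero-initialized) — the averaging doubles as the stabilizer
    of the message dynamics; there is no separate damping factor.
    """
    S = np.asarray(S, dtype=np.float64)
    L = S.shape[0]
    Sp = S.copy()
    np.fill_diagonal(Sp, preferences)
    w = smoothing_window
    lam = (w - 1.0) / w

    # r(i,k) = s(i,k) - max_{k' != k} [s(i,k') + a_hat(i,k')]
    if L == 1:
        r = np.zeros((1, 1))
    else:
        A = Sp + state.a_hat
        idx = np.argmax(A, axis=1)
        first = A[np.arange(L), idx]
        A2 = A.copy()
        A2[np.arange(L), idx] = -np.inf
        second = A2.max(axis=1)
        max_excl = np.tile(first[:, None], (1, L))
        max_excl[np.arange(L), idx] = second
        r = Sp - max_excl
    r_hat = lam * state.r_hat + (1.0 - lam) * r

    a = _availability(r_hat)
    a_hat = lam * state.a_hat + (1.0 - lam) * a

    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(a))):
        raise FloatingPointError(
            f"non-finite message at iteration {state.iteration + 1}"
        )

    history = state.history + [(r, a)]
    if len(history) > w:
        history = history[-w:]
    return MessageState(r=r, a=a, r_hat=r_hat, a_hat=a_hat,
                        history=history, iteration=state.iteration + 1)


def _evidence(state: MessageState) -> np.ndarray:
    """Combined exemplar evidence: smoothed responsibility + availability."""
    return state.r_hat + state.a_hat


def _exemplar_set(state: MessageState) -> np.ndarray:
    """Points whose combined-evidence argmax is themselves."""
    ev = _evidence(state)
    choice = np.argmax(ev, axis=1)
    return np.flatnonzero(choice == np.arange(ev.shape[0]))


def select_exemplars(state: MessageState, S: np.ndarray) -> Partition:
    """Decode the message state into a partition.

    Each point follows the argmax of its smoothed combined message
    evidence (responsibility plus availability, ties to the lowest
    index); points whose argmax is themselves are the exemplars. Points
    pointing at a non-exemplar are redirected once to that target's own
    choice; if still unresolved they fall back to the most similar
    exemplar. If no point selects itself, the point with the largest
    self-evidence becomes the single exemplar.
    """
    ev = _evidence(state)
    L = ev.shape[0]
    choice = np.argmax(ev, axis=1)
    exemplars = np.flatnonzero(choice == np.arange(L))
    if exemplars.size == 0:
        exemplars = np.array([int(np.argmax(np.diag(ev)))])
    ex_mask = np.zeros(L, dtype=bool)
    ex_mask[exemplars] = True

    target = choice.copy()
    target[ex_mask] = np.flatnonzero(ex_mask)
    unresolved = ~ex_mask[target]
    # one chase step through the target's own choice
    target[unresolved] = choice[target[unresolved]]
    unresolved = ~ex_mask[target]
    if unresolved.any():
        sims = np.asarray(S)[np.ix_(np.flatnonzero(unresolved), exemplars)]
        target[unresolved] = exemplars[np.argmax(sims, axis=1)]

    cluster_of = {int(e): c for c, e in enumerate(exemplars)}
    assignment = np.array([cluster_of[int(t)] for t in target], dtype=np.int64)
    return Partition(assignment=assignment, exemplars=exemplars, level=1)


def run_upoap(patch: PatchFeatureSet | np.ndarray,
              config: APConfig = APConfig(),
              sigmas: np.ndarray | None = None) -> Partition:
    """Cluster one point set by optimized affinity propagation.

    Iterates message updates until the exemplar set is unchanged for
    ``convergence_window`` consecutive iterations or ``max_iterations``
    is reached. Fully deterministic.
    """
    S = build_similarity(patch, sigmas=sigmas)
    L = S.shape[0]
    if L == 1:
        return Partition(assignment=np.zeros(1, dtype=np.int64),
                         exemplars=np.zeros(1, dtype=np.int64), level=1)
    preferences = compute_preferences(S, config.preference_mode)
    state = MessageState.zeros(L)
    prev: np.ndarray | None = None
    stable = 0
    for _ in range(config.max_iterations):
        state = ap_step(state, S, preferences, config.smoothing_window)
        current = _exemplar_set(state)
        # the smoothed messages ramp up from zero; stability of the empty
        # candidate set during that ramp does not count as convergence
        if current.size and prev is not None and np.array_equal(current, prev):
            stable += 1
            if stable >= config.convergence_window:
                break
        else:
            stable = 0
        prev = current
    return select_exemplars(state, S)


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------

def _recluster(indices: np.ndarray, features: np.ndarray, sigmas,
               config: APConfig) -> dict[int, int]:
    """Re-cluster the given exemplar voxels; map each to its new exemplar.

    Pools larger than ``max_recluster_size`` are split into deterministic
    contiguous chunks (indices are pre-sorted), each clustered on its own.
    """
    mapping: dict[int, int] = {}
    n = indices.size
    cap = max(2, config.max_recluster_size)
    for s in range(0, n, cap):
        chunk = indices[s:s + cap]
        if chunk.size == 1:
            mapping[int(chunk[0])] = int(chunk[0])
            continue
        part = run_upoap(
            PatchFeatureSet(voxel_indices=chunk, coords=np.zeros((chunk.size, 3)),
                            features=features[chunk], sigmas=np.asarray(sigmas)),
            config=config,
        )
        new_ex = chunk[part.exemplars]
        for local, glob in enumerate(chunk):
            mapping[int(glob)] = int(new_ex[part.assignment[local]])
    return mapping


def hierarchical_refine(level1: Sequence[Partition],
                        patches: Sequence[PatchFeatureSet],
                        features: np.ndarray,
                        config: APConfig = APConfig(),
                        sigmas: np.ndarray | None = None) -> List[Partition]:
    """Merge redundant exemplars across patches; return per-level partitions.

    Level-1 exemplars are pooled and re-clustered (repeatedly, up to
    ``max_hierarchy_levels`` or until the exemplar set stops changing).
    The returned list holds one *global* partition per hierarchy level,
    each assigning every masked voxel: a voxel covered by several patches
    follows its chained exemplar when all covering patches agree, and
    otherwise the candidate exemplar most similar to its own features
    (ties to the lowest voxel index). The cluster count never increases
    from one level to the next.
    """
    if len(level1) == 0:
        raise ValueError("no level-1 partitions")
    if len(level1) != len(patches):
        raise ValueError("one level-1 partition per patch required")
    features = np.asarray(features, dtype=np.float64)
    if sigmas is None:
        sigmas = patches[0].sigmas if patches[0].sigmas is not None \
            else np.ones(features.shape[1])

    n_voxels = features.shape[0]
    # flat (voxel, level-1 exemplar) pairs, one per patch membership
    pair_vox = np.concatenate([p.voxel_indices for p in patches])
    pair_ex = np.concatenate([
        p.voxel_indices[part.exemplars][part.assignment]
        for part, p in zip(level1, patches)
    ])
    covered = np.zeros(n_voxels, dtype=bool)
    covered[pair_vox] = True
    if not covered.all():
        raise ValueError("patches do not cover all masked voxels")

    # chain levels: pool -> top exemplar at each hierarchy level
    exemplar_pool = np.unique(pair_ex)
    chains: List[np.ndarray] = [exemplar_pool.copy()]  # chains[j][i]: top of pool[i]
    current = exemplar_pool
    for _level in range(2, config.max_hierarchy_levels + 1):
        mapping = _recluster(current, features, sigmas, config)
        new = np.unique(np.fromiter(mapping.values(), dtype=np.int64))
        lut = {int(e): mapping[int(t)] for e, t in zip(exemplar_pool, chains[-1])}
        chains.append(np.array([lut[int(e)] for e in exemplar_pool], dtype=np.int64))
        if np.array_equal(np.sort(new), np.sort(current)):
            break
        current = new

    sig = np.asarray(sigmas, dtype=np.float64)
    sig = np.where(sig > 0, sig, np.inf)
    pool_pos = np.searchsorted(exemplar_pool, pair_ex)
    partitions: List[Partition] = []
    for level, chain in enumerate(chains, start=1):
        top = chain[pool_pos]  # per-pair top-level exemplar
        # distance of each voxel to its candidate exemplar, then the most
        # similar candidate wins (ties to the lowest exemplar index)
        d = np.abs((features[pair_vox] - features[top]) / sig).sum(axis=1)
        order = np.lexsort((top, d, pair_vox))
        sv = pair_vox[order]
        keep = np.ones(sv.size, dtype=bool)
        keep[1:] = sv[1:] != sv[:-1]
        vox_ex = np.empty(n_voxels, dtype=np.int64)
        vox_ex[sv[keep]] = top[order][keep]
        exemplars = np.unique(vox_ex)
        assignment = np.searchsorted(exemplars, vox_ex)
        partitions.append(Partition(assignment=assignment, exemplars=exemplars,
                                    level=level))
    return partitions


def levine_nazif_score(partition: Partition, features: np.ndarray,
                       sigmas: np.ndarray | None = None) -> float:
    """Partition-quality score: inter-cluster separation over intra spread.

    ``score = inter / (1 + intra)`` where ``intra`` is the mean distance
    of each point to its cluster's exemplar and ``inter`` the mean
    pairwise distance between exemplars (0 for a single cluster);
    distances are sigma-normalized Manhattan. Merging near-duplicate
    exemplars removes their near-zero pairs and so raises ``inter``,
    while over-merging raises ``intra``; the score peaks at the balanced
    partition.
    """
    features = np.asarray(features, dtype=np.float64)
    if partition.assignment.shape[0] != features.shape[0]:
        raise ValueError("assignment does not cover the feature rows")
    if partition.n_clusters == 0:
        raise ValueError("empty partition")
    if sigmas is None:
        sigmas = np.ones(features.shape[1])
    sigmas = np.asarray(sigmas, dtype=np.float64)
    usable = np.where(sigmas > 0, sigmas, np.inf)
    ex_feats = features[partition.exemplars]
    point_ex = ex_feats[partition.assignment]
    intra = float(np.mean(np.abs((features - point_ex) / usable).sum(axis=1)))
    k = partition.n_clusters
    if k == 1:
        inter = 0.0
    else:
        # mean over unordered exemplar pairs, accumulated in row blocks to
        # bound memory for partitions with many clusters
        total = 0.0
        block = max(1, int(2**22 / max(k, 1)))
        for s in range(0, k, block):
            total += float(pairwise_distance(ex_feats[s:s + block], ex_feats,
                                             sigmas).sum())
        inter = total / (k * (k - 1))
    return inter / (1.0 + intra)


def select_optimal_partition(candidates: Sequence[Partition], features: np.ndarray,
                             sigmas: np.ndarray | None = None) -> Partition:
    """Return the candidate with the highest separation score.

    Exact ties go to the earliest (shallowest-level) candidate.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    scores = [levine_nazif_score(p, features, sigmas) for p in candidates]
    return candidates[int(np.argmax(scores))]
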