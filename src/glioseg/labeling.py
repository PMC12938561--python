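"""Cluster-to-subregion assignment from radiological intensity priors.

The clustering stage produces anonymous tissue clusters. These are mapped
to the three glioma subregions purely by their *relative* mean-intensity
ranks across modalities — no absolute thresholds:

* enhancing tumor (ET): highest mean T1ce (contrast enhancement),
* edema: highest FLAIR (averaged with T2 when present) among the rest,
* necrosis: the remaining, jointly darkest on T1ce and FLAIR.

With more than three clusters, three anchor clusters are picked by the
same extremal ranks and every other cluster joins its nearest anchor
profile. With two clusters only ET and edema are assigned; a single
cluster is labeled edema (whole-lesion fallback). The derived composites
are the standard evaluation regions: TC (tumor core) = ET + necrosis,
WT (whole tumor) = ET + necrosis + edema.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from glioseg.upoap import Partition
from glioseg.volume_io import (
    BACKGROUND, EDEMA, ENHANCING, NECROSIS,
    BinaryMask, LabelVolume, MultiModalVolume,
)


@dataclass
class ClusterProfile:
    """Mean normalized intensity per modality over one cluster's voxels."""

    cluster_id: int
    means: Dict[str, float]
    voxel_count: int

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("profile requires at least one voxel")

    def vector(self, modalities: Sequence[str]) -> np.ndarray:
        return np.array([self.means[m] for m in modalities])


def cluster_profiles(partition: Partition, volume: MultiModalVolume,
                     coords: np.ndarray) -> List[ClusterProfile]:
    """One mean-intensity profile per nonempty cluster.

    ``coords`` are the masked-voxel coordinates the partition's assignment
    refers to; means are taken over each cluster's voxels in each
    available modality.
    """
    if partition.assignment.size == 0:
        raise ValueError("empty partition")
    if coords.shape[0] != partition.assignment.shape[0]:
        raise ValueError("coords do not match the assignment length")
    ix = tuple(np.asarray(coords).T)
    values = {m: volume.data[m][ix] for m in volume.modalities}
    profiles: List[ClusterProfile] = []
    for c in range(partition.n_clusters):
        sel = partition.assignment == c
        n = int(sel.sum())
        if n == 0:
            continue
        profiles.append(ClusterProfile(
            cluster_id=c,
            means={m: float(values[m][sel].mean()) for m in volume.modalities},
            voxel_count=n,
        ))
    return profiles


def _edema_score(p: ClusterProfile) -> float:
    """FLAIR mean, averaged with T2 when T2 is present."""
    if "T2" in p.means:
        return 0.5 * (p.means["FLAIR"] + p.means["T2"])
    return p.means["FLAIR"]


def assign_labels(profiles: Sequence[ClusterProfile]) -> Dict[int, int]:
    """Map each cluster id to a subregion code by relative intensity rank.

    Rank-based and therefore invariant to positive rescaling of any
    modality and to permutation of cluster ids. Ties resolve to the
    lowest cluster id.
    """
    if len(profiles) == 0:
        raise ValueError("no cluster profiles")
    profiles = sorted(profiles, key=lambda p: p.cluster_id)

    if len(profiles) == 1:
        return {profiles[0].cluster_id: EDEMA}

    by_t1ce = max(profiles, key=lambda p: (p.means["T1ce"], -p.cluster_id))
    rest = [p for p in profiles if p.cluster_id != by_t1ce.cluster_id]

    if len(profiles) == 2:
        return {by_t1ce.cluster_id: ENHANCING, rest[0].cluster_id: EDEMA}

    edema_anchor = max(rest, key=lambda p: (_edema_score(p), -p.cluster_id))
    remaining = [p for p in rest if p.cluster_id != edema_anchor.cluster_id]

    if len(profiles) == 3:
        return {
            by_t1ce.cluster_id: ENHANCING,
            edema_anchor.cluster_id: EDEMA,
            remaining[0].cluster_id: NECROSIS,
        }

    # > 3 clusters: anchor the three extremal profiles, attach the rest
    necro_anchor = min(remaining,
                       key=lambda p: (p.means["T1ce"] + p.means["FLAIR"], p.cluster_id))
    anchors = {
        ENHANCING: by_t1ce,
        EDEMA: edema_anchor,
        NECROSIS: necro_anchor,
    }
    modalities = list(profiles[0].means)
    vecs = np.array([p.vector(modalities) for p in profiles])
    sig = vecs.std(axis=0)
    sig = np.where(sig > 0, sig, np.inf)
    mapping: Dict[int, int] = {}
    for p in profiles:
        hit = next((lab for lab, a in anchors.items() if a.cluster_id == p.cluster_id), None)
        if hit is not None:
            mapping[p.cluster_id] = hit
            continue
        dists = {
            lab: float(np.abs((p.vector(modalities) - a.vector(modalities)) / sig).sum())
            for lab, a in anchors.items()
        }
        mapping[p.cluster_id] = min(dists, key=lambda lab: (dists[lab], lab))
    return mapping


def labels_from_partition(partition: Partition, volume: MultiModalVolume,
                          coords: np.ndarray,
                          profile_csv: str | None = None) -> LabelVolume:
    """Label every masked voxel via profiles + rank assignment.

    When ``profile_csv`` is given, the per-cluster mean-intensity table
    (with the assigned subregion) is written there for inspection.
    """
    profiles = cluster_profiles(partition, volume, coords)
    mapping = assign_labels(profiles)
    if profile_csv is not None:
        profiles_dataframe(profiles, mapping).to_csv(profile_csv, index=False)
    grid = np.zeros(volume.shape, dtype=np.int16)
    codes = np.array([mapping.get(c, BACKGROUND) for c in range(partition.n_clusters)],
                     dtype=np.int16)
    grid[tuple(np.asarray(coords).T)] = codes[partition.assignment]
    return LabelVolume(grid, spacing=volume.spacing)


LABEL_NAMES = {BACKGROUND: "background", NECROSIS: "necrosis",
               EDEMA: "edema", ENHANCING: "enhancing"}


def profiles_dataframe(profiles: Sequence[ClusterProfile],
                       mapping: Dict[int, int] | None = None):
    """Per-cluster profile table: mean intensity per modality, voxel count,
    and (when a mapping is given) the assigned subregion name."""
    import pandas as pd

    rows = []
    for p in sorted(profiles, key=lambda q: q.cluster_id):
        row = {"cluster": p.cluster_id, "voxels": p.voxel_count}
        row.update({f"mean_{m}": v for m, v in p.means.items()})
        if mapping is not None:
            row["label"] = LABEL_NAMES[mapping[p.cluster_id]]
        rows.append(row)
    return pd.DataFrame(rows)


def compose_regions(labels: LabelVolume) -> Dict[str, BinaryMask]:
    """Standard evaluation composites: ET, TC = ET+necrosis, WT = all."""
    d = labels.data
    return {
        "ET": BinaryMask(d == ENHANCING, spacing=labels.spacing),
        "TC": BinaryMask((d == ENHANCING) | (d == NECROSIS), spacing=labels.spacing),
        "WT": BinaryMask(d > BACKGROUND, spacing=labels.spacing),
    }
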