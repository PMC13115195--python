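"""Pose ranking and 1-D hierarchical clustering on binding energies.

After scoring, the K lowest-energy poses are retained (single pass,
bounded memory) and agglomeratively clustered on the 1-D distance
|Eᵢ − Eⱼ|.  The default cut removes the hierarchy's final merge(s) —
equivalently, it splits the sorted energies at the largest adjacent
gap — which recovers "a few well-separated binding positions" without
fixing the number of clusters a priori; a fixed-k cut is available.
Each cluster is reported through its representative: the member of
minimum energy, ties broken by lowest original index.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

__all__ = ["ScoredPose", "RankedPoseSet", "EnergyClusters",
           "TopKSelector", "retain_top_k", "cluster_by_energy"]


@dataclass(frozen=True)
class ScoredPose:
    """One retained entry: proposal id, opaque pose payload, energy."""

    pose_id: int
    payload: Any
    energy: float


@dataclass
class RankedPoseSet:
    """The K lowest-energy poses seen, sorted ascending by
    (energy, pose_id)."""

    entries: list[ScoredPose]
    k: int

    def __post_init__(self) -> None:
        if len(self.entries) > self.k:
            raise ValueError("more entries than retention size K")
        keys = [(e.energy, e.pose_id) for e in self.entries]
        if keys != sorted(keys):
            raise ValueError("entries are not sorted by (energy, pose_id)")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def energies(self) -> np.ndarray:
        return np.array([e.energy for e in self.entries])

    @property
    def best(self) -> ScoredPose:
        return self.entries[0]


class TopKSelector:
    """Bounded-size selection of the K smallest (energy, pose_id) keys
    over a stream; order of arrival does not affect the result."""

    def __init__(self, k: int):
        if k < 1:
            raise ValueError(f"K must be >= 1, got {k}")
        self.k = k
        # max-heap via negated keys: root = current worst retained
        self._heap: list[tuple[float, int, Any]] = []

    def update(self, pose_ids: Sequence[int], energies: Sequence[float],
               payloads: Sequence[Any]) -> None:
        for pid, en, pl in zip(pose_ids, energies, payloads):
            key = (-float(en), -int(pid))
            if len(self._heap) < self.k:
                heapq.heappush(self._heap, (*key, pl))
            elif key > self._heap[0][:2]:
                heapq.heapreplace(self._heap, (*key, pl))

    def result(self) -> RankedPoseSet:
        entries = sorted(
            (ScoredPose(pose_id=-nk1, payload=pl, energy=-nk0)
             for nk0, nk1, pl in self._heap),
            key=lambda e: (e.energy, e.pose_id),
        )
        return RankedPoseSet(entries=entries, k=self.k)


def retain_top_k(stream: Iterable[tuple[Any, float]], k: int) -> RankedPoseSet:
    """Retain the K lowest-energy poses from ``stream`` of
    ``(payload, energy)`` pairs, ids assigned by arrival order."""
    sel = TopKSelector(k)
    for i, (payload, energy) in enumerate(stream):
        sel.update([i], [energy], [payload])
    return sel.result()


@dataclass
class EnergyClusters:
    """A partition of entries by binding energy.

    ``labels`` are 1-based and ordered so cluster 1 has the lowest
    representative energy; ``representatives`` maps each label to the
    index of its minimum-energy member (ties: lowest index).
    """

    labels: np.ndarray
    representatives: dict[int, int]
    linkage: str = "single"
    merge_heights: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def cluster_by_energy(energies: Sequence[float], linkage: str = "single",
                      cut: str = "gap", k: int | None = None
                      ) -> EnergyClusters:
    """Agglomerative clustering of scalar energies.

    Parameters
    ----------
    energies : binding energies, kJ mol⁻¹.
    linkage : "single" | "complete" | "average".
    cut : "gap" (default) cuts just below the maximal merge height,
        undoing every merge at that height — for 1-D data this is the
        partition obtained by splitting the sorted energies at the
        largest adjacent gap(s); "k" cuts at a fixed cluster count.
    k : required when ``cut == "k"``.
    """
    e = np.asarray(list(energies), dtype=float)
    if e.ndim != 1 or e.size == 0:
        raise ValueError("need a non-empty 1-D list of energies")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = e.size
    if n == 1:
        return EnergyClusters(labels=np.array([1]), representatives={1: 0},
                              linkage=linkage)
    Z = scipy_linkage(e[:, None], method=linkage)
    heights = Z[:, 2]
    if cut == "gap":
        hmax = heights[-1]
        if hmax <= 1e-12:  # all energies identical
            raw = np.ones(n, dtype=int)
        else:
            below = heights[heights < hmax - 1e-12]
            second = below.max() if below.size else 0.0
            raw = fcluster(Z, t=(second + hmax) / 2.0, criterion="distance")
    elif cut == "k":
        if k is None or k < 1:
            raise ValueError("cut='k' requires a positive k")
        raw = fcluster(Z, t=min(k, n), criterion="maxclust")
    else:
        raise ValueError(f"unknown cut criterion {cut!r}")

    # deterministic relabelling: cluster 1 = lowest representative energy
    reps_raw: dict[int, int] = {}
    for lab in np.unique(raw):
        idx = np.flatnonzero(raw == lab)
        reps_raw[int(lab)] = int(idx[np.argmin(e[idx])])
    order = sorted(reps_raw, key=lambda lab: (e[reps_raw[lab]], reps_raw[lab]))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in raw])
    representatives = {remap[old]: reps_raw[old] for old in order}
    return EnergyClusters(labels=labels, representatives=representatives,
                          linkage=linkage, merge_heights=heights)
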