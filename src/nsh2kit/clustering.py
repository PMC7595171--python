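"""GROMOS conformational clustering and umbrella-window seed selection.

The GROMOS algorithm clusters frames greedily on a pairwise-RMSD matrix:
the frame with the most neighbors within the cutoff becomes a cluster
center, the cluster (center plus neighbors) is removed, and the procedure
repeats until no frames remain.  The cutoff is chosen per group of frames
as the abscissa of the first local maximum of the (smoothed) pairwise-RMSD
histogram.  Window seeding partitions a pulling trace into reaction-
coordinate intervals and returns, per interval, the center of the largest
cluster as the umbrella-window starting frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .analysis import _check_fit_selection, _kabsch
from .constants import nm_to_angstrom
from .ensembles import SelectionSpec, StructureEnsemble

__all__ = [
    "Clustering",
    "rmsd_matrix",
    "gromos_cluster",
    "choose_cutoff",
    "seed_windows",
    "write_clustering",
]


def rmsd_matrix(ensemble: StructureEnsemble, selection: SelectionSpec) -> np.ndarray:
    """Symmetric frames x frames matrix of pairwise least-squares RMSD (A).

    Entry (i, j) is the RMSD of frame j fitted onto frame i over the
    selection.  The Kabsch fit makes the matrix symmetric to numerical
    precision; the triangle inequality may be violated only within that
    tolerance because each pair is fitted independently.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames")
    idx = selection.resolve(ensemble)
    coords = ensemble.coordinates[:, idx, :]
    _check_fit_selection(coords[0], "rmsd_matrix")
    n = len(coords)
    centered = coords - coords.mean(axis=1, keepdims=True)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rot = _kabsch(centered[j], centered[i])
            diff = centered[j] @ rot.T - centered[i]
            out[i, j] = out[j, i] = nm_to_angstrom(
                np.sqrt((diff**2).sum(axis=1).mean())
            )
    return out


@dataclass
class Clustering:
    """Ordered clusters over a frame set.

    Clusters are emitted in extraction order (sizes non-increasing for the
    greedy GROMOS procedure); each holds its center frame index and all
    member indices (center included).
    """

    centers: list
    members: list  # list of lists of frame indices
    cutoff: float  # Angstrom

    def __post_init__(self):
        seen = [i for mem in self.members for i in mem]
        if len(seen) != len(set(seen)):
            raise ValueError("clusters overlap")

    @property
    def sizes(self):
        return [len(m) for m in self.members]


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> Clustering:
    """Greedy neighbor-count clustering on a pairwise-RMSD matrix.

    Ties in the neighbor count are broken toward the lowest frame index,
    which makes the output deterministic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    remaining = np.ones(n, dtype=bool)
    centers, members = [], []
    within = matrix <= cutoff
    while remaining.any():
        idx = np.flatnonzero(remaining)
        counts = within[np.ix_(idx, idx)].sum(axis=1)  # includes self
        center = idx[int(np.argmax(counts))]  # argmax -> lowest index on ties
        mem = idx[within[center, idx]]
        centers.append(int(center))
        members.append([int(i) for i in mem])
        remaining[mem] = False
    return Clustering(centers=centers, members=members, cutoff=float(cutoff))


def choose_cutoff(matrix: np.ndarray, log: list | None = None) -> float:
    """Clustering cutoff from the pairwise-RMSD distribution.

    Histograms all off-diagonal RMSD values (Freedman-Diaconis bin width),
    smooths with a 3-bin moving average, and returns the abscissa of the
    first local maximum.  A distribution with no interior maximum falls back
    to the median with a logged warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(matrix.shape[0], k=1)
    values = matrix[iu]
    if values.size < 10:
        raise ValueError(f"need at least 10 pairwise values, got {values.size}")
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    if iqr > 0:
        width = 2.0 * iqr / values.size ** (1.0 / 3.0)
        n_bins = max(3, int(np.ceil(np.ptp(values) / width))) if np.ptp(values) > 0 else 3
    else:
        n_bins = 3
    hist, edges = np.histogram(values, bins=n_bins)
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    for i in range(len(smooth) - 1):  # the last bin alone is not a relative max
        left_ok = i == 0 or smooth[i] > smooth[i - 1]
        if left_ok and smooth[i] >= smooth[i + 1]:
            return float(centers[i])
    if log is not None:
        log.append("no interior maximum in the RMSD distribution; using median")
    return float(np.median(values))


def seed_windows(trace_values: np.ndarray, ensemble: StructureEnsemble,
                 selection: SelectionSpec, n_windows: int,
                 window_range: tuple[float, float], log: list | None = None):
    """One umbrella-window seed frame per reaction-coordinate interval.

    ``trace_values[t]`` is the reaction-coordinate value of frame ``t`` of
    the pulling trace.  Frames are partitioned into ``n_windows`` uniform
    intervals over ``window_range``; within each interval the member frames
    are clustered (GROMOS, with the per-interval cutoff from
    :func:`choose_cutoff`) and the center of the largest cluster is the
    window's seed.  Intervals too small to histogram (fewer than 10 frame
    pairs) fall back to the median pair distance as cutoff; one- or
    two-frame intervals take the first frame.
    """
    trace_values = np.asarray(trace_values, dtype=float)
    if len(trace_values) != ensemble.n_frames:
        raise ValueError("trace length differs from ensemble frame count")
    lo, hi = window_range
    if not (trace_values.min() <= lo and trace_values.max() >= hi):
        raise ValueError("pull trace does not span the window range")
    edges = np.linspace(lo, hi, n_windows + 1)
    seeds = []
    for w in range(n_windows):
        upper_inclusive = w == n_windows - 1
        in_win = (trace_values >= edges[w]) & (
            trace_values <= edges[w + 1] if upper_inclusive
            else trace_values < edges[w + 1]
        )
        frames = np.flatnonzero(in_win)
        if frames.size == 0:
            raise ValueError(
                f"window interval [{edges[w]:.4g}, {edges[w + 1]:.4g}] contains no frames"
            )
        if frames.size <= 2:
            seeds.append(int(frames[0]))
            continue
        sub = StructureEnsemble(
            coordinates=ensemble.coordinates[frames],
            residue_numbers=ensemble.residue_numbers,
            residue_names=ensemble.residue_names,
            atom_names=ensemble.atom_names,
            provenance=f"{ensemble.provenance}[window {w}]",
        )
        mat = rmsd_matrix(sub, selection)
        n_pairs = frames.size * (frames.size - 1) // 2
        if n_pairs >= 10:
            cutoff = choose_cutoff(mat, log=log)
        else:
            iu = np.triu_indices(frames.size, k=1)
            cutoff = float(np.median(mat[iu]))
            if cutoff <= 0:
                cutoff = 1e-6
            if log is not None:
                log.append(f"window {w}: too few pairs for a histogram; median cutoff")
        clustering = gromos_cluster(mat, cutoff)
        seeds.append(int(frames[clustering.centers[0]]))
    return seeds


def write_clustering(clustering: Clustering, path) -> None:
    doc = {
        "cutoff_angstrom": clustering.cutoff,
        "clusters": [
            {"center": c, "members": m}
            for c, m in zip(clustering.centers, clustering.members)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
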