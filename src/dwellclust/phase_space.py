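"""Phase-space summaries of dwell-time sequence clusters.

Each cluster is a point in the N-dimensional space of dwell-times: its
center is the template (the mean of the member sequences), its occupancy
the fraction of all extracted sequences it absorbed, and its extent the
per-dimension member dispersion.  Distances between centers are plain
Euclidean ("multidimensional Pythagorean") distances in ms.  The 3-D
rendering draws each cluster as a sphere whose volume grows with the
logarithm of its rescaled occupancy, with an orthographic dot projection
onto the tau1-tau3 plane.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_io import Cluster, DwellSequence, ValidationError

log = logging.getLogger(__name__)

__all__ = ["ClusterSummary", "summarize", "pairwise_distances", "render_phase_space"]

#: occupancy above which a cluster counts as a dominant route
DOMINANT_OCCUPANCY = 0.05


@dataclass
class ClusterSummary:
    center: np.ndarray
    cardinality: int
    occupancy_fraction: float
    dispersion: np.ndarray
    start_state: str
    dominant: bool


def summarize(
    clusters: list[Cluster],
    total_sequences: int,
    sequences: list[DwellSequence] | None = None,
) -> list[ClusterSummary]:
    """Per-cluster center/occupancy/dispersion summaries.

    Dispersion (per-dimension standard deviation of the members) needs the
    sequence pool; without it the dispersion of a summary is zero, as it
    is for singletons.  Clusters above 5% occupancy are flagged dominant.
    """
    by_origin = {s.origin_index: s.values for s in sequences} if sequences else {}
    out = []
    for c in clusters:
        if by_origin and len(c.members) > 1:
            vals = np.array([by_origin[m] for m in c.members])
            disp = vals.std(axis=0)
        else:
            disp = np.zeros_like(c.template)
        occ = c.cardinality / total_sequences
        out.append(
            ClusterSummary(
                center=c.template.copy(),
                cardinality=c.cardinality,
                occupancy_fraction=occ,
                dispersion=disp,
                start_state=c.start_state,
                dominant=occ > DOMINANT_OCCUPANCY,
            )
        )
    return out


def pairwise_distances(centers) -> np.ndarray:
    """Symmetric Euclidean distance matrix between cluster centers (ms)."""
    arr = np.asarray(centers, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("centers must be a 2-d array (clusters x dimensions)")
    return squareform(pdist(arr))


def _sphere_radius(occupancy: float, scale: float) -> float:
    volume = np.log1p(scale * occupancy)
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def render_phase_space(
    summaries_by_condition: dict[str, list[ClusterSummary]],
    path,
    dims: tuple[int, int, int] = (1, 2, 3),
    scale: float = 100.0,
) -> None:
    """Render cluster centers as spheres in 3-D dwell-time space.

    ``dims`` are 1-based coordinate indices.  Sphere volume is
    log(1 + scale * occupancy); each condition gets one color; centers are
    orthographically projected as dots onto the tau1-tau3 (floor) plane.
    Conditions with no occupied clusters are skipped with a warning.
    Purely a side effect — no numeric result depends on this.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    d = [i - 1 for i in dims]
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    cmap = plt.get_cmap("tab10")
    pts = []
    for ci, (label, summaries) in enumerate(summaries_by_condition.items()):
        summaries = [s for s in summaries if s.occupancy_fraction > 0]
        if not summaries:
            warnings.warn(f"condition {label!r} has no occupied clusters; skipped")
            continue
        for s in summaries:
            if len(s.center) < max(dims):
                raise ValidationError(
                    f"cluster center has {len(s.center)} dims, need {max(dims)}"
                )
        xyz = np.array([[s.center[i] for i in d] for s in summaries])
        radii = [_sphere_radius(s.occupancy_fraction, scale) for s in summaries]
        ax.scatter(
            xyz[:, 0], xyz[:, 1], xyz[:, 2],
            s=[200 * r**2 for r in radii],
            color=cmap(ci % 10), alpha=0.7, label=label, depthshade=True,
        )
        pts.append(xyz)
    if pts:
        allp = np.vstack(pts)
        for ci, xyz in enumerate(pts):
            ax.scatter(
                xyz[:, 0], xyz[:, 1], np.full(len(xyz), 0.0),
                marker=".", s=12, color=cmap(ci % 10), alpha=0.5,
            )
        ax.set_zlim(0.0, max(1e-6, allp[:, 2].max() * 1.1))
    ax.set_xlabel(f"tau{dims[0]} (ms)")
    ax.set_ylabel(f"tau{dims[1]} (ms)")
    ax.set_zlabel(f"tau{dims[2]} (ms)")
    if summaries_by_condition:
        ax.legend(loc="upper left", fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    log.info("phase-space figure written to %s", path)
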