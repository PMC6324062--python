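"""Bilayer geometry: leaflet assignment, flip-flop detection, head-group RDF
and annular shells, and per-leaflet surface / thickness / deformation maps.

Leaflets are the two large connected components of a spatial-proximity graph
over phosphate beads (minimum-image distances laterally, z non-periodic).
A graph rather than a z-threshold is used so curved or locally deformed
bilayers are assigned consistently.  Thickness is measured phosphate
surface to phosphate surface; deformation is local thickness minus the bulk
(far-from-protein) thickness.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._geom import distance_matrix, lateral_distance_matrix
from .beads import BeadClass
from .errors import NonBilayerError
from .frames import CGFrame

__all__ = [
    "Leaflet",
    "LeafletAssignment",
    "LeafletRecord",
    "FlipFlopEvent",
    "RadialDistribution",
    "MembraneSurfaces",
    "assign_leaflets",
    "detect_flipflops",
    "headgroup_rdf",
    "leaflet_surfaces",
    "local_thickness_per_residue",
]

LEAFLET_GRAPH_CUTOFF = 15.0  # Å, phosphate-phosphate adjacency
PERSISTENCE_FRAMES = 5
R_BULK_FALLBACK = 25.0  # Å, bulk annulus when no RDF shell boundary is known


class Leaflet(str, Enum):
    UPPER = "UPPER"
    LOWER = "LOWER"


@dataclass
class LeafletAssignment:
    """Leaflet label per phosphate-bearing lipid for one frame."""

    labels: dict[int, Leaflet]  # lipid_id -> leaflet
    frame_index: int = 0

    def lipids(self, leaflet: Leaflet) -> list[int]:
        return sorted(l for l, lab in self.labels.items() if lab is leaflet)


@dataclass
class LeafletRecord:
    """Per-lipid leaflet history across frames."""

    lipid_id: int
    frames: list[int]
    leaflets: list[Leaflet]


@dataclass
class FlipFlopEvent:
    """A persistent change of leaflet by one lipid.

    ``start_frame`` is the first frame after the lipid's previous stable run;
    ``end_frame`` is the first frame of the new stable run (equal when the
    transition is instantaneous).  The new label persists for at least
    ``persistence_frames`` frames from ``end_frame``.
    """

    lipid_id: int
    from_leaflet: Leaflet
    to_leaflet: Leaflet
    start_frame: int
    end_frame: int

    def __post_init__(self):
        if self.from_leaflet == self.to_leaflet:
            raise ValueError("flip-flop must change leaflet")

    def overlaps(self, first_frame: int, last_frame: int) -> bool:
        return self.start_frame <= last_frame and self.end_frame >= first_frame


def assign_leaflets(
    frame: CGFrame,
    cutoff: float = LEAFLET_GRAPH_CUTOFF,
    frame_index: int = 0,
    min_component_fraction: float = 0.05,
) -> LeafletAssignment:
    """Label every phosphate-bearing lipid UPPER or LOWER.

    Builds the phosphate proximity graph at ``cutoff`` and takes its two
    large connected components as the leaflets (UPPER = greater mean z).
    Small satellite components (e.g. a lipid caught mid-flip near the
    midplane) are attached to the component of their nearest phosphate
    neighbour.  Raises :class:`NonBilayerError` when the number of large
    components is not exactly 2.
    """
    lipid_ids, pos = frame.phosphate_positions()
    n = len(lipid_ids)
    if n < 2:
        raise ValueError(f"need >= 2 phosphate-bearing lipids, got {n}")

    dmat = distance_matrix(pos, pos, frame.box)
    adj = (dmat < cutoff) & ~np.eye(n, dtype=bool)
    ii, jj = np.nonzero(adj)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, comp = connected_components(graph, directed=False)

    sizes = np.bincount(comp, minlength=n_comp)
    min_size = max(2, int(np.ceil(min_component_fraction * n)))
    large = np.flatnonzero(sizes >= min_size)
    if len(large) != 2:
        raise NonBilayerError(len(large))

    # attach small components via the nearest phosphate in a large component
    large_mask = np.isin(comp, large)
    resolved = comp.copy()
    for k in np.flatnonzero(~large_mask):
        d = dmat[k].copy()
        d[~large_mask] = np.inf
        resolved[k] = comp[int(np.argmin(d))]

    mean_z = [pos[resolved == c, 2].mean() for c in large]
    upper = large[int(np.argmax(mean_z))]
    labels = {
        int(lipid_ids[k]): (Leaflet.UPPER if resolved[k] == upper else Leaflet.LOWER)
        for k in range(n)
    }
    return LeafletAssignment(labels=labels, frame_index=frame_index)


def leaflet_history(assignments: list[LeafletAssignment]) -> list[LeafletRecord]:
    """Reshape per-frame assignments into per-lipid records."""
    ids = sorted(assignments[0].labels)
    return [
        LeafletRecord(
            lipid_id=i,
            frames=[a.frame_index for a in assignments],
            leaflets=[a.labels[i] for a in assignments],
        )
        for i in ids
    ]


def _stable_runs(labels: list[Leaflet], persistence: int):
    """Maximal constant runs, keeping those of length >= persistence.

    The first run is the initial condition and is always stable.
    """
    runs = []  # (label, start, length)
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - start))
            start = i
    return [
        r for k, r in enumerate(runs) if k == 0 or r[2] >= persistence
    ]


def detect_flipflops(
    records: list[LeafletRecord],
    persistence_frames: int = PERSISTENCE_FRAMES,
) -> list[FlipFlopEvent]:
    """Find persistent leaflet changes; single-frame flickers emit nothing."""
    events: list[FlipFlopEvent] = []
    for rec in records:
        if len(rec.frames) < persistence_frames + 1:
            raise ValueError(
                f"need >= persistence_frames + 1 = {persistence_frames + 1} frames"
            )
        stable = _stable_runs(rec.leaflets, persistence_frames)
        for prev, cur in zip(stable, stable[1:]):
            if prev[0] == cur[0]:
                continue
            prev_end = prev[1] + prev[2] - 1  # last frame of previous stable run
            events.append(
                FlipFlopEvent(
                    lipid_id=rec.lipid_id,
                    from_leaflet=prev[0],
                    to_leaflet=cur[0],
                    start_frame=rec.frames[prev_end + 1],
                    end_frame=rec.frames[cur[1]],
                )
            )
    return events


@dataclass
class RadialDistribution:
    """Head-group RDF about the protein surface with annular-shell minima."""

    bin_edges: np.ndarray  # Å, len = n_bins + 1
    g: np.ndarray  # normalized density per bin
    counts: np.ndarray  # raw phosphate counts per bin
    shell_boundaries: np.ndarray  # Å, radii of the first k minima of smoothed g

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def headgroup_rdf(
    frame: CGFrame,
    bin_width: float = 1.0,
    r_max: float = 40.0,
    smoothing_bins: int = 3,
    n_shells: int = 2,
) -> RadialDistribution:
    """RDF of lipid phosphates as a function of distance to the protein surface.

    r for each lipid is the minimum-image distance from its phosphate bead to
    the nearest protein bead.  g(r) is normalized by the mean projected
    phosphate density rho = N_phos / (Lx * Ly) times the annulus area
    2*pi*r*dr; for a uniform bilayer this makes g -> 1 at large r (the
    per-leaflet z-offset Jacobian cancels exactly).  Shell boundaries are the
    radii of the first ``n_shells`` local minima of the moving-average
    smoothed g beyond its first maximum.
    """
    if r_max > min(frame.box[0], frame.box[1]) / 2:
        raise ValueError(
            f"r_max={r_max} exceeds half the smallest lateral box edge "
            f"({min(frame.box[0], frame.box[1]) / 2:.1f} Å)"
        )
    prot = frame.coordinates[frame.class_mask(BeadClass.PROTEIN)]
    _, phos = frame.phosphate_positions()
    if len(prot) == 0 or len(phos) == 0:
        raise ValueError("frame must contain protein beads and phosphate beads")

    d = distance_matrix(phos, prot, frame.box).min(axis=1)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts, _ = np.histogram(d, bins=edges)

    rho = len(phos) / (frame.box[0] * frame.box[1])
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    expected = rho * 2.0 * np.pi * r_mid * bin_width
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)

    g_s = uniform_filter1d(g, size=max(1, smoothing_bins), mode="nearest")
    peak = int(np.argmax(g_s))
    minima = [
        i
        for i in range(peak + 1, len(g_s) - 1)
        if g_s[i] < g_s[i - 1] and g_s[i] <= g_s[i + 1]
    ]
    boundaries = np.asarray([r_mid[i] for i in minima[:n_shells]])
    return RadialDistribution(
        bin_edges=edges, g=g, counts=counts, shell_boundaries=boundaries
    )


@dataclass
class MembraneSurfaces:
    """Gridded leaflet surfaces, thickness and deformation maps (all Å)."""

    grid_spacing: float
    x_centers: np.ndarray
    y_centers: np.ndarray
    upper_z: np.ndarray  # (nx, ny), NaN where unsupported
    lower_z: np.ndarray
    thickness: np.ndarray  # upper_z - lower_z, exactly
    bulk_thickness: float
    deformation: np.ndarray  # thickness - bulk_thickness
    bulk_mask: np.ndarray = field(default=None)

    def midplane_z(self) -> np.ndarray:
        return 0.5 * (self.upper_z + self.lower_z)

    def defined(self) -> np.ndarray:
        return np.isfinite(self.thickness)


def _grid_centers(L: float, spacing: float) -> np.ndarray:
    n = max(1, int(round(L / spacing)))
    h = L / n
    return (np.arange(n) + 0.5) * h


def _surface_grid(points, box, xc, yc, bandwidth):
    """Gaussian-weighted mean z of ``points`` on the lateral grid."""
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    cells = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    d = lateral_distance_matrix(cells, points, box)
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    w[d > 3.0 * bandwidth] = 0.0
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w @ points[:, 2]) / wsum
    z[wsum <= 0] = np.nan
    return z.reshape(gx.shape)


def leaflet_surfaces(
    frame: CGFrame,
    leaflets: LeafletAssignment,
    grid_spacing: float = 2.0,
    bandwidth: float = 5.0,
    r_bulk: float | None = None,
) -> MembraneSurfaces:
    """Reconstruct per-leaflet phosphate surfaces on a lateral grid.

    Each cell's surface height is the Gaussian-weighted (bandwidth sigma,
    3-sigma support cutoff, lateral minimum image) mean phosphate z of its
    leaflet.  Bulk thickness is the mean thickness over cells farther than
    ``r_bulk`` (default: the fallback bulk radius; pass the second annular
    shell boundary from :func:`headgroup_rdf` when available) from any
    protein bead.
    """
    lip_ids, phos = frame.phosphate_positions()
    up = np.asarray([leaflets.labels[int(l)] is Leaflet.UPPER for l in lip_ids])
    if not up.any() or up.all():
        raise ValueError("one of the leaflets is empty")

    xc = _grid_centers(frame.box[0], grid_spacing)
    yc = _grid_centers(frame.box[1], grid_spacing)
    upper = _surface_grid(phos[up], frame.box, xc, yc, bandwidth)
    lower = _surface_grid(phos[~up], frame.box, xc, yc, bandwidth)
    thickness = upper - lower

    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    cells = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    prot = frame.coordinates[frame.class_mask(BeadClass.PROTEIN)]
    if len(prot):
        dprot = lateral_distance_matrix(cells, prot, frame.box).min(axis=1)
    else:
        dprot = np.full(len(cells), np.inf)
    dprot = dprot.reshape(gx.shape)

    r0 = R_BULK_FALLBACK if r_bulk is None else float(r_bulk)
    defined = np.isfinite(thickness)
    bulk_mask = (dprot > r0) & defined
    if not bulk_mask.any():
        _warnings.warn(
            "no grid cells beyond the bulk radius; using the 25% of defined "
            "cells farthest from the protein",
            stacklevel=2,
        )
        dd = np.where(defined, dprot, -np.inf).ravel()
        k = max(1, int(0.25 * defined.sum()))
        thresh = np.sort(dd)[-k]
        bulk_mask = (dprot >= thresh) & defined

    valid = bulk_mask & np.isfinite(thickness)
    bulk = float(np.mean(thickness[valid])) if valid.any() else float("nan")
    return MembraneSurfaces(
        grid_spacing=grid_spacing,
        x_centers=xc,
        y_centers=yc,
        upper_z=upper,
        lower_z=lower,
        thickness=thickness,
        bulk_thickness=bulk,
        deformation=thickness - bulk,
        bulk_mask=bulk_mask,
    )


def surface_value_at(
    surfaces: MembraneSurfaces, xy: np.ndarray, grid: np.ndarray, box: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-defined-cell lookup of a surface grid at lateral points.

    Returns (values, lateral distance to the supporting cell).
    """
    defined = np.isfinite(grid)
    gx, gy = np.meshgrid(surfaces.x_centers, surfaces.y_centers, indexing="ij")
    cells = np.column_stack([gx[defined], gy[defined], np.zeros(defined.sum())])
    vals = grid[defined]
    pts = np.column_stack([np.atleast_2d(xy), np.zeros(len(np.atleast_2d(xy)))])
    d = lateral_distance_matrix(pts, cells, box)
    idx = d.argmin(axis=1)
    return vals[idx], d[np.arange(len(pts)), idx]


def local_thickness_per_residue(
    frame: CGFrame, surfaces: MembraneSurfaces
):
    """Per protein residue: depth above the local midplane and local thickness.

    Depth is the residue z (backbone bead, else bead centroid) minus the
    midplane z of the nearest defined grid cell.  Residues laterally outside
    every supported cell (farther than 1.5 grid spacings from the nearest
    defined cell) fall back to the bulk thickness and are flagged in the
    ``outside_support`` column.
    """
    import pandas as pd

    res = frame.protein_residues()
    if res.empty:
        return pd.DataFrame(
            columns=[
                "chain_id", "residue_index", "residue_name", "x", "y", "z",
                "depth", "local_thickness", "outside_support",
            ]
        )
    xy = res[["x", "y"]].to_numpy()
    thick, d_thick = surface_value_at(surfaces, xy, surfaces.thickness, frame.box)
    mid, _ = surface_value_at(surfaces, xy, surfaces.midplane_z(), frame.box)
    outside = d_thick > 1.5 * surfaces.grid_spacing
    thick = np.where(outside, surfaces.bulk_thickness, thick)

    out = res.copy()
    out["depth"] = res["z"].to_numpy() - mid
    out["local_thickness"] = thick
    out["outside_support"] = outside
    return out
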