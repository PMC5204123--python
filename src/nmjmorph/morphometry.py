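"""The 21 morphometric variables of one en-face NMJ.

Eleven *core* variables come straight off the binary masks and the
skeleton: areas, perimeters, branch tallies, endplate extent, cluster
count.  Seven *derived* variables are recomputed from the core ones (never
stored independently): average branch length, complexity
(log10 of branches x branch points x total length), average cluster area,
fragmentation (1 - 1/k for k clusters), compactness (% of the endplate
region occupied by AChR), overlap (% of AChR area contacted by nerve
terminal) and the area of synaptic contact itself.  Three *associated*
variables (axon diameter, muscle fibre diameter, number of axonal inputs)
are manual annotations, not mask measurements.

The endplate region - the area enclosed by a perimeter traced around the
outer limits of the AChR clusters - defaults to the convex hull of the
AChR foreground; an alpha-shape alternative is available for crescent
endplates that a hull would overestimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .image_io import Annotations, BinaryMask, META_COLUMNS, NMJImagePair, NMJMeta
from .segmentation import ClusterLabels, SkeletonStats

__all__ = [
    "MorphometricRecord",
    "TABLE_COLUMNS",
    "CORE_VARIABLES",
    "DERIVED_VARIABLES",
    "ASSOCIATED_VARIABLES",
    "measure_area",
    "measure_perimeter",
    "endplate_region",
    "max_feret",
    "complexity",
    "fragmentation",
    "compactness",
    "synaptic_contact",
    "overlap",
    "measure_line",
    "assemble_record",
    "records_to_frame",
    "frame_from_csv_columns",
]

SQRT2 = math.sqrt(2.0)


class MorphometryError(ValueError):
    pass


@dataclass(frozen=True)
class MorphometricRecord:
    """The 21 variables for one NMJ, plus its identity metadata.

    Annotation-derived fields (axon/fibre diameter, axonal inputs) and any
    index undefined for a degenerate junction are ``None``, never 0.
    """

    # core, pre-synaptic
    nerve_terminal_area: float
    nerve_terminal_perimeter: float
    n_terminal_branches: int
    n_branch_points: int
    total_branch_length: float
    # core, post-synaptic
    achr_area: float
    achr_perimeter: float
    endplate_area: float
    endplate_perimeter: float
    endplate_diameter: float
    n_achr_clusters: int
    # derived
    avg_branch_length: Optional[float]
    complexity: Optional[float]
    avg_achr_cluster_area: Optional[float]
    fragmentation: Optional[float]
    compactness: Optional[float]
    overlap: Optional[float]
    synaptic_contact_area: float
    # associated nerve & muscle
    axon_diameter: Optional[float] = None
    muscle_fibre_diameter: Optional[float] = None
    n_axon_inputs: Optional[int] = None
    meta: NMJMeta = NMJMeta()


#: CSV column name for each record field, in spreadsheet order.
TABLE_COLUMNS: dict[str, str] = {
    "nerve_terminal_area": "(1) nerve terminal area (um^2)",
    "nerve_terminal_perimeter": "(2) nerve terminal perimeter (um)",
    "n_terminal_branches": "(3) number terminal branches",
    "n_branch_points": "(4) number branch points",
    "total_branch_length": "(5) total length branches (um)",
    "achr_area": "(6) AChR area (um^2)",
    "achr_perimeter": "(7) AChR perimeter (um)",
    "endplate_area": "(8) endplate area (um^2)",
    "endplate_perimeter": "(9) endplate perimeter (um)",
    "endplate_diameter": "(10) endplate diameter (um)",
    "n_achr_clusters": "(11) number AChR clusters",
    "avg_branch_length": "(12) average length branches (um)",
    "complexity": "(13) complexity",
    "avg_achr_cluster_area": "(14) average area AChR clusters (um^2)",
    "fragmentation": "(15) fragmentation",
    "compactness": "(16) compactness (%)",
    "overlap": "(17) overlap (%)",
    "synaptic_contact_area": "(18) area of synaptic contact (um^2)",
    "axon_diameter": "(19) axon diameter (um)",
    "muscle_fibre_diameter": "(20) muscle fibre diameter (um)",
    "n_axon_inputs": "(21) number of axonal inputs",
}

CORE_VARIABLES = list(TABLE_COLUMNS)[:11]
DERIVED_VARIABLES = list(TABLE_COLUMNS)[11:18]
ASSOCIATED_VARIABLES = list(TABLE_COLUMNS)[18:]


def measure_area(mask: BinaryMask) -> float:
    """Foreground area in square micrometres (pixel count x pixel_size^2)."""
    return mask.area_px * mask.pixel_size**2


def measure_perimeter(mask: BinaryMask) -> float:
    """Boundary length of all foreground components, in micrometres.

    Crack-boundary estimator with a diagonal correction:
    ``P = C - (2 - sqrt 2) * D`` in pixel units, where C is the number of
    foreground/background pixel edges (cracks, image border included) and D
    counts diagonal boundary configurations over all 2x2 windows - a window
    with exactly two diagonally placed foreground pixels adds 2 (both sides
    of the staircase are cut), a window with exactly three adds 1.  The
    estimator is exact for axis-aligned rectangles (a single pixel measures
    4 crack units) and asymptotically exact for 45-degree staircases.
    """
    px = mask.pixels
    if not px.any():
        return 0.0
    p = np.pad(px, 1)
    cracks = 0
    cracks += int(np.sum(p[1:, :] != p[:-1, :]))
    cracks += int(np.sum(p[:, 1:] != p[:, :-1]))
    # 2x2 window census
    a = p[:-1, :-1].astype(np.uint8)
    b = p[:-1, 1:].astype(np.uint8)
    c = p[1:, :-1].astype(np.uint8)
    d = p[1:, 1:].astype(np.uint8)
    total = a + b + c + d
    diag2 = (total == 2) & (a == d) & (b == c) & (a != b)
    three = total == 3
    d_count = 2 * int(diag2.sum()) + int(three.sum())
    return (cracks - (2.0 - SQRT2) * d_count) * mask.pixel_size


def _hull_of(mask: BinaryMask) -> Optional[ConvexHull]:
    pts = np.argwhere(mask.pixels).astype(float)
    if len(pts) < 3:
        return None
    try:
        return ConvexHull(pts)
    except QhullError:  # collinear foreground
        return None


def endplate_region(
    achr_mask: BinaryMask, mode: str = "hull", alpha: float = 0.1
) -> BinaryMask:
    """Filled region enclosing the outer limits of all AChR clusters.

    ``mode="hull"`` (default) fills the convex hull of the AChR foreground;
    ``mode="alpha"`` fills an alpha-shape (tighter for crescent endplates),
    with ``alpha`` the inverse circumradius cutoff in 1/px: Delaunay
    triangles with circumradius <= 1/alpha are kept.  The AChR mask is
    always a subset of the result.
    """
    if achr_mask.area_px == 0:
        raise MorphometryError("endplate region of an empty AChR mask")
    if mode == "hull":
        from skimage.morphology import convex_hull_image

        region = convex_hull_image(achr_mask.pixels)
    elif mode == "alpha":
        region = _alpha_shape_fill(achr_mask.pixels, alpha)
    else:
        raise MorphometryError(f"unknown endplate-region mode {mode!r}")
    region = region | achr_mask.pixels
    return BinaryMask(region, achr_mask.pixel_size)


def _alpha_shape_fill(px: np.ndarray, alpha: float) -> np.ndarray:
    """Rasterized alpha-shape of the foreground pixel centers."""
    from scipy.spatial import Delaunay

    pts = np.argwhere(px).astype(float)
    if len(pts) < 4:
        return px.copy()
    try:
        tri = Delaunay(pts)
    except QhullError:
        return px.copy()
    out = px.copy()
    rr, cc = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
    grid = np.column_stack([rr.ravel(), cc.ravel()])
    simplex = tri.find_simplex(grid)
    keep = np.zeros(len(tri.simplices), dtype=bool)
    for i, s in enumerate(tri.simplices):
        pa, pb, pc = pts[s]
        la, lb, lc = (
            np.linalg.norm(pb - pc),
            np.linalg.norm(pa - pc),
            np.linalg.norm(pa - pb),
        )
        u, v = pb - pa, pc - pa
        area2 = abs(u[0] * v[1] - u[1] * v[0])
        if area2 <= 0:
            continue
        circum_r = la * lb * lc / (2.0 * area2)
        keep[i] = circum_r <= 1.0 / alpha
    inside = (simplex >= 0) & keep[np.clip(simplex, 0, None)]
    out |= inside.reshape(px.shape)
    return out


def max_feret(mask: BinaryMask) -> float:
    """Maximum Feret (caliper) diameter across the foreground, in µm.

    The maximum pairwise distance between foreground pixel centers,
    evaluated on convex hull vertices.  A single pixel has diameter 0.
    """
    if mask.area_px == 0:
        raise MorphometryError("Feret diameter of an empty mask")
    hull = _hull_of(mask)
    if hull is None:
        pts = np.argwhere(mask.pixels).astype(float)
    else:
        pts = hull.points[hull.vertices]
    if len(pts) == 1:
        return 0.0
    diff = pts[:, None, :] - pts[None, :, :]
    dmax = float(np.sqrt((diff**2).sum(-1)).max())
    return dmax * mask.pixel_size


def complexity(n_branches: int, n_branch_points: int, total_length: float) -> float:
    """Single pre-synaptic branching index:
    log10(branches x branch points x total length [µm]).

    Undefined (raises) when any factor is non-positive; callers should
    withhold the value for degenerate arbors rather than record 0.
    """
    if n_branches <= 0 or n_branch_points <= 0 or total_length <= 0:
        raise MorphometryError(
            "complexity undefined: needs positive branch count, branch-point "
            "count and total length"
        )
    return math.log10(n_branches * n_branch_points * total_length)


def fragmentation(n_clusters: int) -> float:
    """Endplate fragmentation index 1 - 1/k for k discrete AChR clusters.

    A solid plaque (k = 1) scores exactly 0; the index approaches but never
    reaches 1 as the endplate fragments.
    """
    if n_clusters < 1:
        raise MorphometryError("fragmentation needs at least one cluster")
    return 1.0 - 1.0 / n_clusters


def compactness(achr_area: float, endplate_area: float) -> float:
    """Percentage of the enclosed endplate region occupied by AChR signal."""
    if endplate_area <= 0:
        raise MorphometryError("compactness undefined for zero endplate area")
    if achr_area > endplate_area * (1 + 1e-9):
        raise MorphometryError(
            "inconsistent masks: AChR area exceeds endplate area"
        )
    return 100.0 * achr_area / endplate_area


def synaptic_contact(terminal_mask: BinaryMask, achr_mask: BinaryMask) -> float:
    """Area of synaptic contact: the terminal/AChR mask intersection, µm²."""
    if terminal_mask.shape != achr_mask.shape:
        raise MorphometryError("mask shapes differ")
    if terminal_mask.pixel_size != achr_mask.pixel_size:
        raise MorphometryError("mask calibrations differ")
    inter = terminal_mask.pixels & achr_mask.pixels
    return int(inter.sum()) * terminal_mask.pixel_size**2


def overlap(contact_area: float, achr_area: float) -> float:
    """Percentage occupancy of AChRs by the nerve terminal."""
    if achr_area <= 0:
        raise MorphometryError("overlap undefined for zero AChR area")
    if contact_area > achr_area * (1 + 1e-9):
        raise MorphometryError("contact area exceeds AChR area")
    return 100.0 * contact_area / achr_area


def measure_line(p1, p2, pixel_size: float) -> float:
    """Length of a manually drawn line (axon or fibre diameter), in µm."""
    d = math.dist(p1, p2) * pixel_size
    if d == 0:
        warnings.warn("measure_line: coincident endpoints, length 0")
    return d


def assemble_record(
    pair: NMJImagePair,
    terminal_mask: BinaryMask,
    achr_mask: BinaryMask,
    skeleton_stats: SkeletonStats,
    clusters: ClusterLabels,
    endplate_mask: Optional[BinaryMask] = None,
    endplate_mode: str = "hull",
    alpha: float = 0.1,
) -> MorphometricRecord:
    """Compute all derivable variables for one NMJ and validate invariants.

    Derived indices are recomputed from the core measurements here; they
    are never taken from upstream.  Annotation-derived fields (19)-(21) are
    filled only when annotations are present.  A violated invariant raises
    :class:`MorphometryError` naming the offending field.
    """
    if terminal_mask.area_px == 0:
        raise MorphometryError("nerve_terminal_area: terminal mask is empty")
    if achr_mask.area_px == 0:
        raise MorphometryError("achr_area: AChR mask is empty")

    nt_area = measure_area(terminal_mask)
    nt_perim = measure_perimeter(terminal_mask)
    achr_area_v = measure_area(achr_mask)
    achr_perim = measure_perimeter(achr_mask)
    if endplate_mask is None:
        endplate_mask = endplate_region(achr_mask, mode=endplate_mode, alpha=alpha)
    ep_area = measure_area(endplate_mask)
    ep_perim = measure_perimeter(endplate_mask)
    ep_diam = max_feret(endplate_mask)

    n_br = skeleton_stats.n_terminal_branches
    n_bp = skeleton_stats.n_branch_points
    tot_len = skeleton_stats.total_length
    k = clusters.n_clusters
    if k < 1:
        raise MorphometryError("n_achr_clusters: no clusters in a non-empty mask")

    avg_len = tot_len / n_br if n_br > 0 else None
    try:
        cx = complexity(n_br, n_bp, tot_len)
    except MorphometryError:
        cx = None
    contact = synaptic_contact(terminal_mask, achr_mask)
    rec = MorphometricRecord(
        nerve_terminal_area=nt_area,
        nerve_terminal_perimeter=nt_perim,
        n_terminal_branches=n_br,
        n_branch_points=n_bp,
        total_branch_length=tot_len,
        achr_area=achr_area_v,
        achr_perimeter=achr_perim,
        endplate_area=ep_area,
        endplate_perimeter=ep_perim,
        endplate_diameter=ep_diam,
        n_achr_clusters=k,
        avg_branch_length=avg_len,
        complexity=cx,
        avg_achr_cluster_area=achr_area_v / k,
        fragmentation=fragmentation(k),
        compactness=compactness(achr_area_v, ep_area),
        overlap=overlap(contact, achr_area_v),
        synaptic_contact_area=contact,
        axon_diameter=_annotation_axon_diameter(pair),
        muscle_fibre_diameter=_annotation_fibre_diameter(pair),
        n_axon_inputs=pair.annotations.n_axon_inputs,
        meta=pair.meta,
    )
    _validate(rec)
    return rec


def _annotation_axon_diameter(pair: NMJImagePair) -> Optional[float]:
    line = pair.annotations.axon_line
    if line is None:
        return None
    return measure_line(line[0], line[1], pair.pixel_size)


def _annotation_fibre_diameter(pair: NMJImagePair) -> Optional[float]:
    lines = pair.annotations.fibre_lines
    if not lines:
        return None
    return float(
        np.mean([measure_line(a, b, pair.pixel_size) for a, b in lines])
    )


def _validate(rec: MorphometricRecord) -> None:
    def _bad(field: str, msg: str):
        raise MorphometryError(f"{field}: {msg}")

    nonneg = [
        "nerve_terminal_area",
        "nerve_terminal_perimeter",
        "n_terminal_branches",
        "n_branch_points",
        "total_branch_length",
        "achr_area",
        "achr_perimeter",
        "endplate_area",
        "endplate_perimeter",
        "endplate_diameter",
        "n_achr_clusters",
        "synaptic_contact_area",
    ]
    for f in nonneg:
        if getattr(rec, f) < 0:
            _bad(f, "negative")
    if rec.fragmentation is not None and not (0.0 <= rec.fragmentation < 1.0):
        _bad("fragmentation", "outside [0, 1)")
    if rec.compactness is not None and not (0.0 < rec.compactness <= 100.0 + 1e-9):
        _bad("compactness", "outside (0, 100]")
    if rec.overlap is not None and not (0.0 <= rec.overlap <= 100.0 + 1e-9):
        _bad("overlap", "outside [0, 100]")
    if rec.synaptic_contact_area > min(rec.nerve_terminal_area, rec.achr_area) * (
        1 + 1e-9
    ):
        _bad("synaptic_contact_area", "exceeds a parent mask area")


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate records: metadata columns then the 21 variable columns."""
    rows = []
    for rec in records:
        row = {
            "animal": rec.meta.animal,
            "muscle": rec.meta.muscle,
            "side": rec.meta.side,
            "nmj": rec.meta.nmj,
        }
        for fname, col in TABLE_COLUMNS.items():
            row[col] = getattr(rec, fname)
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + list(TABLE_COLUMNS.values()))


def frame_from_csv_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Rename spreadsheet columns back to record field names (inverse of
    :func:`records_to_frame` naming)."""
    inv = {col: fname for fname, col in TABLE_COLUMNS.items()}
    return df.rename(columns=inv)
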