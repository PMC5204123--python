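"""Synthetic en-face NMJ image pairs with exact ground truth.

The generator emulates the geometry the measurement pipeline cares about,
not microscope physics: a branching nerve-terminal ribbon drawn as a random
planar tree (random-walk segments with bounded turning, splitting until a
target endpoint count is reached), dilated to a terminal mask; an AChR
plaque as a wider dilation of the same tree, carved into a controllable
number of discrete receptor clusters by removing separator bands between
geodesic cells; both channels rendered at intensity 200 on a dark
background, Gaussian-blurred and corrupted with additive Gaussian noise,
clipped to 8 bit.

Ground truth is computed from the *pre-noise* masks by the package's own
measurement code (skeleton statistics, areas, hull, indices), so
"pipeline matches truth" isolates exactly the imaging/segmentation losses:
blur, noise and re-thresholding.

Multi-muscle datasets mirror a 9-muscle x 3-mouse x 2-side x 40-NMJ design
in which muscles differ in overall size and cluster count, mice carry a
small random size offset, and the two sides are drawn from the same
distribution (no built-in side effect).  All randomness flows from one
master seed through a documented ``SeedSequence`` splitting scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.morphology import dilation, disk, opening
from skimage.segmentation import watershed

from .image_io import (
    Annotations,
    BinaryMask,
    CalibratedImage,
    NMJImagePair,
    NMJMeta,
    write_image_pair,
)
from .morphometry import MorphometricRecord, assemble_record
from .segmentation import (
    STRUCT8,
    ClusterLabels,
    classify_skeleton,
    segment_clusters,
    skeletonize,
)

__all__ = [
    "MuscleProfile",
    "GroundTruth",
    "DatasetSpec",
    "default_profiles",
    "generate_nmj",
    "generate_dataset",
    "records_to_table",
]

FOREGROUND_INTENSITY = 200


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class MuscleProfile:
    """Morphological envelope for one synthetic muscle's NMJs.

    ``size_scale`` multiplies every linear dimension (walk length, ribbon
    halfwidths), so areas scale with its square.  ``branch_count_range``
    and ``cluster_count_range`` are inclusive integer ranges sampled per
    NMJ.  Halfwidths are in pixels at scale 1; diameters in µm.
    """

    name: str = "SYN"
    size_scale: float = 1.0
    branch_count_range: tuple[int, int] = (18, 34)
    cluster_count_range: tuple[int, int] = (3, 7)
    terminal_halfwidth: float = 3.5
    plaque_halfwidth: float = 6.0
    axon_diameter_mean: float = 2.8
    axon_diameter_sd: float = 0.35
    fibre_diameter_mean: float = 35.0
    fibre_diameter_sd: float = 6.0
    blur_sigma: float = 1.0
    noise_sd: float = 10.0
    background_level: float = 20.0  # detector offset, keeps noise off the clip
    pixel_size: float = 0.25  # µm / px
    canvas: int = 384
    segment_length_px: float = 11.0
    size_jitter_sd: float = 0.15  # lognormal sigma of per-NMJ size factor

    def __post_init__(self) -> None:
        if self.size_scale <= 0:
            raise SynthError("size_scale must be positive")
        for rng_name in ("branch_count_range", "cluster_count_range"):
            lo, hi = getattr(self, rng_name)
            if not (1 <= lo <= hi):
                raise SynthError(f"{rng_name} must be a non-empty range >= 1")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise SynthError("blur/noise parameters must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Pre-noise masks and the record measured from them."""

    terminal_mask: BinaryMask
    achr_mask: BinaryMask
    skeleton: np.ndarray
    n_clusters: int
    record: MorphometricRecord
    size_factor: float  # per-NMJ linear size multiplier actually applied


@dataclass(frozen=True)
class DatasetSpec:
    """A multi-muscle synthetic study design."""

    profiles: tuple = ()
    n_mice: int = 3
    sides: tuple = ("L", "R")
    nmjs_per_sample: int = 40
    seed: int = 0
    mouse_size_sd: float = 0.08  # lognormal sigma of per-mouse size offset

    def __post_init__(self) -> None:
        profiles = self.profiles or default_profiles()
        object.__setattr__(self, "profiles", tuple(profiles))
        if self.n_mice < 1 or self.nmjs_per_sample < 1 or not self.sides:
            raise SynthError("counts must be positive and sides non-empty")

    @property
    def n_total(self) -> int:
        return len(self.profiles) * self.n_mice * len(self.sides) * self.nmjs_per_sample


def default_profiles() -> tuple[MuscleProfile, ...]:
    """Nine synthetic muscles spanning a realistic size / fragmentation range.

    Size scales spread linear dimensions about +/-30% around 1 (so areas
    span roughly a 3-fold range) and per-muscle cluster-count ranges spread
    mean counts from about 3.5 to 7.5, emulating between-muscle
    heterogeneity in overall junction size and endplate fragmentation.
    Axon diameter tracks muscle size; fibre diameter varies more broadly.
    """
    names = ["IS", "LAL", "EPI", "FL2", "FL3", "TRI", "HL1", "HL4", "QUA"]
    scales = np.linspace(0.75, 1.35, 9)
    cluster_ranges = [
        (2, 5), (3, 6), (2, 6), (4, 8), (3, 7), (5, 9), (3, 8), (4, 9), (5, 10),
    ]
    branch_ranges = [
        (14, 24), (15, 26), (16, 28), (17, 29), (18, 30), (19, 32),
        (20, 33), (21, 35), (22, 36),
    ]
    profiles = []
    for i, name in enumerate(names):
        s = float(scales[i])
        profiles.append(
            MuscleProfile(
                name=name,
                size_scale=s,
                branch_count_range=branch_ranges[i],
                cluster_count_range=cluster_ranges[i],
                axon_diameter_mean=2.3 + 1.0 * (s - 0.75) / 0.6,
                axon_diameter_sd=0.3,
                fibre_diameter_mean=18.0 + 39.0 * (s - 0.75) / 0.6,
                fibre_diameter_sd=4.0,
            )
        )
    return tuple(profiles)


# ---------------------------------------------------------------------------
# tree-skeleton construction
# ---------------------------------------------------------------------------


def _grow_tree(
    rng: np.random.Generator, profile: MuscleProfile, n_leaves: int, scale: float
) -> np.ndarray:
    """Rasterize a random planar tree with ~n_leaves endpoint segments.

    Tips carry a leaf quota; a tip with quota > 1 splits into two children
    after its segment.  Steps are sub-pixel (0.7 px) with a bounded random
    turn per step, which yields smooth, pretzel-like ribbons once dilated.
    """
    n = profile.canvas
    margin = int(math.ceil(profile.plaque_halfwidth * scale)) + 6
    grid = np.zeros((n, n), dtype=bool)
    center = n / 2.0
    theta0 = rng.uniform(0, 2 * math.pi)
    # (row, col, heading, leaf quota)
    tips = [(center, center, theta0, max(1, n_leaves))]
    if n_leaves >= 2:  # start with two opposite trunks for a spread arbor
        q = n_leaves // 2
        tips = [
            (center, center, theta0, n_leaves - q),
            (center, center, theta0 + math.pi, q),
        ]
    step = 0.7
    while tips:
        r, c, theta, quota = tips.pop()
        seg_len = profile.segment_length_px * scale * rng.uniform(0.6, 1.4)
        n_steps = max(2, int(seg_len / step))
        alive = True
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.18)
            r += step * math.sin(theta)
            c += step * math.cos(theta)
            if not (margin <= r < n - margin and margin <= c < n - margin):
                alive = False
                break
            grid[int(round(r)), int(round(c))] = True
        if not alive or quota <= 1:
            continue
        q1 = quota // 2
        q2 = quota - q1
        split = rng.uniform(0.45, 0.9)
        tips.append((r, c, theta + split, q1))
        tips.append((r, c, theta - split, q2))
    if not grid.any():
        raise SynthError("profile infeasible: tree left the canvas immediately")
    return grid


def _carve_clusters(
    rng: np.random.Generator,
    plaque: np.ndarray,
    tree: np.ndarray,
    k: int,
    blur_sigma: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Split one plaque into k discrete clusters by removing separator bands.

    Seeds are spread along the tree in raster order of its pixels; cells
    grow geodesically (flood fill from the seeds inside the plaque) and the
    band where cells meet is deleted, wide enough that rendering blur
    cannot re-bridge it.  Returns (mask, labels, actual cluster count).
    """
    if k <= 1:
        labels, _ = ndi.label(plaque, structure=STRUCT8)
        return plaque, labels, int(labels.max())
    coords = np.argwhere(tree & plaque)
    if len(coords) < k:
        coords = np.argwhere(plaque)
    order = rng.permutation(len(coords))[:k]
    markers = np.zeros(plaque.shape, dtype=np.int32)
    for i, idx in enumerate(order, start=1):
        r, c = coords[idx]
        markers[r, c] = i
    cells = watershed(np.zeros_like(plaque, dtype=np.uint8), markers, mask=plaque)
    hi = ndi.maximum_filter(cells, size=3)
    lo = ndi.minimum_filter(np.where(cells > 0, cells, np.int32(1 << 20)), size=3)
    boundary = plaque & (hi != lo)
    sep_half = max(1, int(math.ceil(1.5 * blur_sigma)))
    band = dilation(boundary, disk(sep_half))
    mask = plaque & ~band
    # opening enforces a minimum local cluster width: carving must not leave
    # slivers or necks thinner than the measurement pipeline can resolve
    mask = opening(mask, disk(4))
    # drop crumbs the carving may have isolated
    labels, n = ndi.label(mask, structure=STRUCT8)
    if n:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < 20)
        small = small[small > 0]
        if small.size:
            mask = mask & ~np.isin(labels, small)
            labels, n = ndi.label(mask, structure=STRUCT8)
    return mask, labels.astype(np.int32), int(n)


def _render(mask: np.ndarray, blur_sigma: float, noise_sd: float,
            rng: np.random.Generator, background: float = 20.0) -> np.ndarray:
    """Render a mask as an 8-bit channel: offset background, blur, noise.

    Noise is signal-dependent (shot-noise-like): ``noise_sd`` is the SD at
    full foreground intensity and scales with the square root of the local
    intensity, so the background is correspondingly tighter - as in real
    fluorescence micrographs.
    """
    img = background + mask.astype(np.float64) * (FOREGROUND_INTENSITY - background)
    if blur_sigma > 0:
        img = gaussian(img, sigma=blur_sigma, preserve_range=True)
    if noise_sd > 0:
        sd = noise_sd * np.sqrt(np.maximum(img, 1.0) / FOREGROUND_INTENSITY)
        img = img + rng.normal(0.0, 1.0, size=img.shape) * sd
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_nmj(
    profile: MuscleProfile,
    seed: int | np.random.SeedSequence | None = None,
    meta: Optional[NMJMeta] = None,
    size_multiplier: float = 1.0,
) -> tuple[NMJImagePair, GroundTruth]:
    """Generate one synthetic NMJ image pair with its ground truth.

    ``size_multiplier`` applies an extra linear scale on top of the profile
    (used for per-mouse offsets).  The same seed always produces
    bit-identical images and truth.
    """
    rng = np.random.default_rng(seed)
    g = rng.normal()  # latent per-NMJ size factor, shared with axon diameter
    jitter = math.exp(profile.size_jitter_sd * g)
    scale = profile.size_scale * size_multiplier * jitter

    r_term = max(1, int(round(profile.terminal_halfwidth * scale)))
    r_plaque = max(r_term + 1, int(round(profile.plaque_halfwidth * scale)))
    if 2 * r_plaque + 16 >= profile.canvas:
        raise SynthError("profile infeasible: plaque halfwidth exceeds canvas")

    lo, hi = profile.branch_count_range
    n_branches = int(rng.integers(lo, hi + 1))
    lo_k, hi_k = profile.cluster_count_range
    k_target = int(rng.integers(lo_k, hi_k + 1))

    # The generator's contract is that its AChR clusters are *completely
    # discrete*: on a clean (no blur, no noise) rendering the canonical
    # marker-watershed must resolve exactly the carved components.  Random
    # arbors occasionally self-approach so closely that one carved cluster
    # keeps a thin tangency neck, which even a human rater would call
    # ambiguous; such geometries are resampled.
    terminal = achr = labels = None
    k_actual = -1
    for _ in range(20):
        tree = _grow_tree(rng, profile, n_branches, scale)
        terminal = dilation(tree, disk(r_term))
        plaque = dilation(tree, disk(r_plaque))
        for _ in range(3):  # recarve until it lands exactly on target
            achr, labels, k_actual = _carve_clusters(
                rng, plaque, tree, k_target, profile.blur_sigma
            )
            if k_actual == k_target:
                break
        rows = np.flatnonzero(achr.any(axis=1))
        cols = np.flatnonzero(achr.any(axis=0))
        if rows.size == 0:
            continue
        win = (
            slice(max(0, rows[0] - 4), rows[-1] + 5),
            slice(max(0, cols[0] - 4), cols[-1] + 5),
        )
        clean = CalibratedImage(
            _render(achr[win], 0.0, 0.0, rng, profile.background_level),
            profile.pixel_size,
        )
        resolved = segment_clusters(clean, BinaryMask(achr[win], profile.pixel_size))
        if resolved.n_clusters == k_actual:
            break

    pixel_size = profile.pixel_size
    # annotation lines: axon diameter coupled to the NMJ's own size factor,
    # fibre diameter varying at the muscle level only
    axon_d = max(
        0.3,
        profile.axon_diameter_mean
        + profile.axon_diameter_sd * (0.8 * g + 0.6 * rng.normal()),
    )
    fibre_d = max(5.0, profile.fibre_diameter_mean
                  + profile.fibre_diameter_sd * rng.normal())
    ann = Annotations(
        axon_line=((2.0, 2.0), (2.0, 2.0 + axon_d / pixel_size)),
        fibre_lines=(((4.0, 2.0), (4.0, 2.0 + fibre_d / pixel_size)),),
        n_axon_inputs=1,
    )
    meta = meta or NMJMeta(animal="M1", muscle=profile.name, side="L", nmj=0)
    pair = NMJImagePair(
        terminal=CalibratedImage(
            _render(terminal, profile.blur_sigma, profile.noise_sd, rng,
                    profile.background_level),
            pixel_size, name=f"{profile.name}:terminal"),
        achr=CalibratedImage(
            _render(achr, profile.blur_sigma, profile.noise_sd, rng,
                    profile.background_level),
            pixel_size, name=f"{profile.name}:achr"),
        meta=meta,
        annotations=ann,
    )

    terminal_mask = BinaryMask(terminal, pixel_size)
    achr_mask = BinaryMask(achr, pixel_size)
    skel = skeletonize(terminal_mask)
    stats = classify_skeleton(skel)
    clusters = ClusterLabels(labels, k_actual)
    record = assemble_record(pair, terminal_mask, achr_mask, stats, clusters)
    truth = GroundTruth(
        terminal_mask=terminal_mask,
        achr_mask=achr_mask,
        skeleton=skel.pixels,
        n_clusters=k_actual,
        record=record,
        size_factor=scale,
    )
    return pair, truth


def generate_dataset(
    spec: DatasetSpec,
    out_dir: str | Path | None = None,
    render: Optional[bool] = None,
) -> pd.DataFrame:
    """Generate a whole synthetic study and return its truth table.

    The table has factor columns (muscle, mouse, side, nmj) plus the
    morphometric variables under their record field names.  With
    ``out_dir`` set, every image pair is written as a 2-channel TIFF with a
    JSON sidecar; otherwise images are discarded after truth extraction
    (``render=False`` additionally skips blur/noise rendering work).

    Seeds: NMJ (i, j, s, n) draws from ``SeedSequence([master, i, j, s, n])``
    and the per-mouse size offset from ``SeedSequence([master, 10**6 + j])``,
    so any subset regenerates identically.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    if render is None:
        render = out_dir is not None

    records = []
    for j in range(spec.n_mice):
        mouse_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 10**6 + j])
        )
        mouse_mult = math.exp(spec.mouse_size_sd * mouse_rng.normal())
        for i, profile in enumerate(spec.profiles):
            prof = profile if render else replace(profile, blur_sigma=0.0,
                                                  noise_sd=0.0)
            for s, side in enumerate(spec.sides):
                for n in range(spec.nmjs_per_sample):
                    ss = np.random.SeedSequence([spec.seed, i, j, s, n])
                    meta = NMJMeta(
                        animal=f"M{j + 1}", muscle=profile.name, side=side, nmj=n
                    )
                    pair, truth = generate_nmj(
                        prof, seed=ss, meta=meta, size_multiplier=mouse_mult
                    )
                    records.append(truth.record)
                    if out_dir is not None:
                        write_image_pair(
                            pair,
                            out_dir
                            / f"{profile.name}_M{j + 1}_{side}_{n:03d}.tif",
                        )
    table = records_to_table(records)
    if out_dir is not None:
        table.to_csv(out_dir / "truth.csv", index=False)
    return table


def records_to_table(records: Sequence[MorphometricRecord]) -> pd.DataFrame:
    """Tidy analysis table: factors + snake_case variable columns."""
    from dataclasses import fields

    rows = []
    var_fields = [f.name for f in fields(MorphometricRecord) if f.name != "meta"]
    for rec in records:
        row = {
            "muscle": rec.meta.muscle,
            "mouse": rec.meta.animal,
            "side": rec.meta.side,
            "nmj": rec.meta.nmj,
        }
        row.update({f: getattr(rec, f) for f in var_fields})
        rows.append(row)
    return pd.DataFrame(rows)
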