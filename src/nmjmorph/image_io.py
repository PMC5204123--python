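"""Calibrated image I/O for en-face NMJ micrographs.

The measurement pipeline works on two-channel 8-bit maximum-intensity
projections: channel 1 is the pre-synaptic nerve terminal (neurofilament /
synaptic-vesicle immunolabel), channel 2 the post-synaptic acetylcholine
receptor plaque (alpha-bungarotoxin).  Every image carries an explicit
spatial calibration in micrometres per pixel; nothing downstream assumes a
global pixel size.

Channels are always identified by an explicit channel map, never inferred
from color.  Images deeper than 8 bit are rejected unless the caller asks
for a linear rescale.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibratedImage",
    "NMJImagePair",
    "BinaryMask",
    "NMJMeta",
    "Annotations",
    "max_intensity_projection",
    "read_image_pair",
    "write_image_pair",
    "write_record_csv",
    "read_record_csv",
]


class ImageIOError(ValueError):
    """Raised on contract violations in image reading/writing."""


@dataclass(frozen=True)
class CalibratedImage:
    """A single-channel 8-bit image with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D uint8 array of intensities.
    pixel_size
        Micrometres per pixel; strictly positive.
    name
        Free-text identifier (channel label, file stem, ...).
    """

    pixels: np.ndarray
    pixel_size: float
    name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ImageIOError(f"expected a 2-D image, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ImageIOError(
                f"expected 8-bit intensities (uint8), got {px.dtype}; "
                "use read_image_pair(..., rescale=True) for deeper data"
            )
        if not (self.pixel_size > 0):
            raise ImageIOError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean foreground mask sharing the calibration of its source image."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ImageIOError(f"expected a 2-D mask, got shape {px.shape}")
        if px.dtype != bool:
            px = px.astype(bool)
        if not (self.pixel_size > 0):
            raise ImageIOError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class NMJMeta:
    """Identity of one NMJ: animal, muscle code, body side and index."""

    animal: str = ""
    muscle: str = ""
    side: str = ""
    nmj: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("", "L", "R"):
            raise ImageIOError(f"side must be 'L' or 'R', got {self.side!r}")


@dataclass(frozen=True)
class Annotations:
    """Manual annotations attached to one NMJ image pair.

    ``axon_line`` / ``fibre_lines`` are pixel-coordinate endpoint pairs laid
    across the axon or muscle fibre; lengths are measured downstream with the
    image calibration.  ``n_axon_inputs`` is a manual count of axons entering
    the junction.  ``oblique_fraction`` flags how much of the NMJ is tilted
    out of the imaging plane (the tool records, it does not measure, this).
    """

    axon_line: Optional[tuple[tuple[float, float], tuple[float, float]]] = None
    fibre_lines: tuple = ()
    n_axon_inputs: Optional[int] = None
    oblique_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_axon_inputs is not None and self.n_axon_inputs < 1:
            raise ImageIOError("n_axon_inputs must be >= 1 when present")
        if not (0.0 <= self.oblique_fraction <= 1.0):
            raise ImageIOError("oblique_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class NMJImagePair:
    """Two-channel en-face NMJ image: nerve terminal + AChR plaque."""

    terminal: CalibratedImage
    achr: CalibratedImage
    meta: NMJMeta = field(default_factory=NMJMeta)
    annotations: Annotations = field(default_factory=Annotations)

    def __post_init__(self) -> None:
        if self.terminal.shape != self.achr.shape:
            raise ImageIOError(
                f"channel shapes differ: {self.terminal.shape} vs {self.achr.shape}"
            )
        if self.terminal.pixel_size != self.achr.pixel_size:
            raise ImageIOError("channel calibrations differ")

    @property
    def pixel_size(self) -> float:
        return self.terminal.pixel_size


def max_intensity_projection(stack: Sequence[CalibratedImage]) -> CalibratedImage:
    """Collapse a z-stack to its per-pixel maximum.

    All slices must share shape and calibration.  A single-slice stack
    projects to itself (idempotence).
    """
    if len(stack) == 0:
        raise ImageIOError("cannot project an empty stack")
    first = stack[0]
    for sl in stack[1:]:
        if sl.shape != first.shape:
            raise ImageIOError("stack slices have mismatched shapes")
        if sl.pixel_size != first.pixel_size:
            raise ImageIOError("stack slices have mismatched calibrations")
    proj = np.max(np.stack([sl.pixels for sl in stack]), axis=0)
    return CalibratedImage(proj, first.pixel_size, name=first.name)


def _rescale_to_uint8(arr: np.ndarray) -> np.ndarray:
    """Linear rescale of an integer image to the full 8-bit range."""
    info = np.iinfo(arr.dtype)
    return (arr.astype(np.float64) * (255.0 / info.max)).round().astype(np.uint8)


def read_image_pair(
    path: str | Path,
    channel_map: Mapping[int, str],
    pixel_size: Optional[float] = None,
    meta: Optional[NMJMeta] = None,
    annotations: Optional[Annotations] = None,
    rescale: bool = False,
) -> NMJImagePair:
    """Read a multi-channel TIFF into an :class:`NMJImagePair`.

    ``channel_map`` maps 1-based channel indices to the roles ``"terminal"``
    and ``"achr"``, e.g. ``{1: "terminal", 2: "achr"}``.  Calibration must be
    supplied either via ``pixel_size`` or a JSON sidecar ``<path>.json``
    (which may also carry metadata and annotations); absent calibration is a
    hard error.  Images deeper than 8 bit are rejected unless
    ``rescale=True`` requests a linear rescale to 0-255.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    sidecar = _read_sidecar(path)
    if pixel_size is None:
        pixel_size = sidecar.get("pixel_size")
    if pixel_size is None:
        raise ImageIOError(
            f"no pixel calibration for {path}: pass pixel_size= or provide a "
            f"JSON sidecar {path.name}.json with a 'pixel_size' key"
        )
    if meta is None and "meta" in sidecar:
        meta = NMJMeta(**sidecar["meta"])
    if annotations is None and "annotations" in sidecar:
        annotations = _annotations_from_dict(sidecar["annotations"])

    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - depends on corruption mode
        raise ImageIOError(f"unreadable TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ImageIOError(f"expected (C, H, W) or (H, W) data, got {arr.shape}")
    # channel axis first; tifffile may deliver (H, W, C) for RGB-style files
    if arr.shape[-1] <= 4 and arr.shape[0] > 4:
        arr = np.moveaxis(arr, -1, 0)
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ImageIOError(f"unsupported dtype {arr.dtype}")
        if not rescale:
            raise ImageIOError(
                f"{path} is {arr.dtype}, not 8-bit; pass rescale=True to "
                "linearly rescale"
            )
        arr = _rescale_to_uint8(arr)

    roles = {role: idx for idx, role in channel_map.items()}
    if set(roles) != {"terminal", "achr"}:
        raise ImageIOError(
            f"channel_map must name exactly 'terminal' and 'achr', got {channel_map}"
        )
    channels = {}
    for role, idx in roles.items():
        if not (1 <= idx <= arr.shape[0]):
            raise ImageIOError(
                f"channel {idx} ({role}) not present: file has {arr.shape[0]} channel(s)"
            )
        channels[role] = CalibratedImage(
            arr[idx - 1], float(pixel_size), name=f"{path.stem}:{role}"
        )
    return NMJImagePair(
        terminal=channels["terminal"],
        achr=channels["achr"],
        meta=meta or NMJMeta(),
        annotations=annotations or Annotations(),
    )


def write_image_pair(pair: NMJImagePair, path: str | Path) -> Path:
    """Write a pair as a 2-channel TIFF (terminal first) plus JSON sidecar."""
    path = Path(path)
    stack = np.stack([pair.terminal.pixels, pair.achr.pixels])
    tifffile.imwrite(path, stack)
    sidecar = {
        "pixel_size": pair.pixel_size,
        "meta": dataclasses.asdict(pair.meta),
        "annotations": _annotations_to_dict(pair.annotations),
    }
    Path(f"{path}.json").write_text(json.dumps(sidecar, indent=1))
    return path


def _read_sidecar(path: Path) -> dict:
    sc = Path(f"{path}.json")
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def _annotations_to_dict(ann: Annotations) -> dict:
    return {
        "axon_line": ann.axon_line,
        "fibre_lines": list(ann.fibre_lines),
        "n_axon_inputs": ann.n_axon_inputs,
        "oblique_fraction": ann.oblique_fraction,
    }


def _annotations_from_dict(d: Mapping) -> Annotations:
    def _line(obj):
        if obj is None:
            return None
        (a, b) = obj
        return (tuple(float(x) for x in a), tuple(float(x) for x in b))

    return Annotations(
        axon_line=_line(d.get("axon_line")),
        fibre_lines=tuple(_line(l) for l in d.get("fibre_lines", ())),
        n_axon_inputs=d.get("n_axon_inputs"),
        oblique_fraction=d.get("oblique_fraction", 0.0),
    )


# ---------------------------------------------------------------------------
# Record CSV
# ---------------------------------------------------------------------------

#: Metadata columns preceding the 21 morphometric variables.
META_COLUMNS = ["animal", "muscle", "side", "nmj"]


def write_record_csv(records, path: str | Path, provenance: str | None = None) -> Path:
    """Collate morphometric records into one spreadsheet (CSV).

    One row per NMJ; metadata columns first, then the 21 variable columns
    under their standard names.  Absent values (e.g. annotation-derived
    fields never measured) are written as empty cells, never as zeros.
    ``provenance`` lines, if given, are prepended as ``#`` comments.
    """
    from .morphometry import records_to_frame  # local import: avoid cycle

    if len(records) == 0:
        raise ImageIOError("no records to write")
    frame = records_to_frame(records)
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            for line in provenance.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)
    return path


def read_record_csv(path: str | Path) -> pd.DataFrame:
    """Read back a record CSV (skipping ``#`` provenance lines)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        warnings.warn(f"record CSV lacks metadata columns: {missing}")
    return df
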