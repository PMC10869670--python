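"""Reading and writing multi-frame angiographic image stacks.

The in-memory container is :class:`FrameStack`: a ``(frame, row, col)``
float array plus its acquisition :class:`~sdsa.model.TimeGrid` and a
polarity flag.  The canonical internal polarity is ``contrast_bright``
(contrast arrival raises stored intensity); subtracted angiograms usually
render contrast dark, so DICOM input defaults to inversion.

Supported on-disk formats
-------------------------
``dicom_multiframe``
    Multi-frame X-ray angiography DICOM (read only).  Frame rate is taken
    from an explicit override first, then CineRate (0018,0040), then
    FrameTime (0018,1063).
``tiff_stack``
    Multi-page TIFF; acquisition metadata is stored as a JSON image
    description so round trips are lossless.
``raw_array``
    A ``.npy`` voxel array next to a plain-text JSON sidecar
    (``<path>.json``) holding ``n_frames``, ``frame_rate``, ``origin``,
    ``polarity`` and ``source_id``.  Used as the test-fixture format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .model import TimeGrid

__all__ = ["FrameStack", "read_stack", "write_stack", "POLARITIES", "FORMATS"]

POLARITIES = ("contrast_bright", "contrast_dark")
FORMATS = ("dicom_multiframe", "tiff_stack", "raw_array")


@dataclass
class FrameStack:
    """An ordered multi-frame 2-D image series with acquisition metadata."""

    voxels: np.ndarray
    grid: TimeGrid
    polarity: str = "contrast_bright"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"voxels must be (frame, row, col), got shape {self.voxels.shape}"
            )
        if self.voxels.shape[0] != self.grid.n_frames:
            raise ValueError(
                f"frame count {self.voxels.shape[0]} != grid.n_frames {self.grid.n_frames}"
            )
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")

    @property
    def n_frames(self) -> int:
        return self.grid.n_frames

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    def to_bright(self) -> "FrameStack":
        """Return a copy normalized to the canonical contrast_bright polarity.

        Dark-contrast stacks are inverted about their global maximum so that
        contrast arrival increases stored intensity and the pre-arrival
        baseline sits near zero.
        """
        if self.polarity == "contrast_bright":
            return self
        inverted = self.voxels.max() - self.voxels
        return FrameStack(inverted, self.grid, "contrast_bright", self.source_id)


def _read_raw_array(path: Path) -> FrameStack:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"raw_array sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    voxels = np.load(path)
    grid = TimeGrid(
        n_frames=int(meta["n_frames"]),
        frame_rate=float(meta["frame_rate"]),
        origin=float(meta.get("origin", 0.0)),
    )
    return FrameStack(voxels, grid, meta.get("polarity", "contrast_bright"),
                      meta.get("source_id", str(path)))


def _read_tiff(path: Path, frame_rate: float | None) -> FrameStack:
    with tifffile.TiffFile(path) as tif:
        voxels = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if voxels.ndim == 2:
        voxels = voxels[None]
    fps = frame_rate if frame_rate is not None else meta.get("frame_rate")
    if fps is None:
        raise ValueError(
            f"{path}: no frame-rate metadata in TIFF description; pass frame_rate"
        )
    grid = TimeGrid(voxels.shape[0], float(fps), float(meta.get("origin", 0.0)))
    return FrameStack(voxels, grid, meta.get("polarity", "contrast_bright"),
                      meta.get("source_id", str(path)))


def _read_dicom(path: Path, frame_rate: float | None) -> FrameStack:
    import pydicom

    ds = pydicom.dcmread(path)
    voxels = ds.pixel_array.astype(float)
    if voxels.ndim == 2:
        voxels = voxels[None]
    fps = frame_rate
    if fps is None and "CineRate" in ds:
        fps = float(ds.CineRate)
    if fps is None and "FrameTime" in ds and float(ds.FrameTime) > 0:
        fps = 1000.0 / float(ds.FrameTime)  # FrameTime is in ms
    if fps is None:
        raise ValueError(
            f"{path}: no CineRate/FrameTime metadata; pass frame_rate explicitly"
        )
    grid = TimeGrid(voxels.shape[0], float(fps))
    # Subtracted angiograms conventionally render contrast dark.
    return FrameStack(voxels, grid, "contrast_dark", str(path))


def read_stack(
    path,
    format: str = "raw_array",
    frame_rate: float | None = None,
    polarity: str | None = None,
) -> FrameStack:
    """Read a multi-frame stack and normalize it to contrast_bright polarity.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"dicom_multiframe", "tiff_stack", "raw_array"}
    frame_rate : float, optional
        Explicit frames-per-second override.  Takes precedence over any
        metadata in the file.
    polarity : {"contrast_bright", "contrast_dark"}, optional
        Override the stored/assumed polarity before normalization.

    Returns
    -------
    FrameStack
        Always in ``contrast_bright`` polarity.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "raw_array":
        stack = _read_raw_array(path)
    elif format == "tiff_stack":
        stack = _read_tiff(path, frame_rate)
    else:
        stack = _read_dicom(path, frame_rate)
    if frame_rate is not None:
        stack = FrameStack(
            stack.voxels,
            TimeGrid(stack.grid.n_frames, float(frame_rate), stack.grid.origin),
            stack.polarity,
            stack.source_id,
        )
    if polarity is not None:
        if polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        stack = FrameStack(stack.voxels, stack.grid, polarity, stack.source_id)
    return stack.to_bright()


def write_stack(stack: FrameStack, path, format: str = "raw_array") -> Path:
    """Write a stack to disk; lossless for tiff_stack and raw_array."""
    path = Path(path)
    if format == "dicom_multiframe":
        raise NotImplementedError("DICOM writing is out of scope")
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    meta = {
        "n_frames": stack.grid.n_frames,
        "frame_rate": stack.grid.frame_rate,
        "origin": stack.grid.origin,
        "polarity": stack.polarity,
        "source_id": stack.source_id,
    }
    if format == "raw_array":
        np.save(path, stack.voxels)
        # np.save appends .npy when missing; mirror that for the sidecar
        actual = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
        sidecar = actual.with_suffix(actual.suffix + ".json")
        sidecar.write_text(json.dumps(meta, indent=1))
        return actual
    tifffile.imwrite(path, stack.voxels, description=json.dumps(meta))
    return path
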