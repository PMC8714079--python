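"""Image containers, z-projections, ROI geometry and TIFF I/O.

Conventions used throughout the package:

* A single image frame is a plain 2-D :class:`numpy.ndarray` indexed
  ``[row, col]`` = ``[y, x]``. Intensities are non-negative, unitless
  camera counts (8- or 16-bit typical).
* Pixel coordinates are 0-based. Rectangles are half-open:
  ``[x0, x0 + width) x [y0, y0 + height)``.
* Points passed around the API are ``(x, y)`` pairs.

:class:`ZStack` holds one timepoint's z-sections, :class:`ImageSeries`
holds a whole recording for one channel together with its frame interval
(10 s in the recordings this package models) and pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "ZStack",
    "ImageSeries",
    "Roi",
    "max_project",
    "sum_project",
    "total_intensity",
    "read_series",
    "write_series",
]


def _validate_frame(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {pixels.shape}")
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise ValueError("frame must have at least one pixel")
    if np.any(pixels < 0):
        raise ValueError("frame contains negative intensities")
    return pixels


@dataclass
class ZStack:
    """An ordered stack of same-shape z-sections for one timepoint.

    Parameters
    ----------
    data : ndarray, shape (Z, Y, X)
        Slice intensities. All slices share one shape; values >= 0.
    z_step_um : float
        Axial step between sections, micrometres (metadata only).
    """

    data: np.ndarray
    z_step_um: float = 0.8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"z-stack must be 3-D (Z, Y, X), got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("empty stack")
        if np.any(self.data < 0):
            raise ValueError("z-stack contains negative intensities")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each slice."""
        return self.data.shape[1:]


@dataclass
class ImageSeries:
    """A time series of z-stacks for one channel.

    ``dt_s`` is the frame interval in seconds (default 10, matching
    spinning-disc acquisition at one stack every 10 s); ``pixel_size_um``
    is the lateral pixel size used to convert distances to micrometres.
    """

    stacks: list[ZStack]
    dt_s: float = 10.0
    pixel_size_um: float = 0.1
    channel: str = ""

    def __post_init__(self) -> None:
        if len(self.stacks) < 1:
            raise ValueError("series must contain at least one timepoint")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        shape0 = self.stacks[0].shape
        for i, st in enumerate(self.stacks):
            if st.shape != shape0:
                raise ValueError(
                    f"timepoint {i} has shape {st.shape}, expected {shape0}"
                )

    def __len__(self) -> int:
        return len(self.stacks)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.stacks[0].shape

    def times_s(self) -> np.ndarray:
        """Acquisition times of each frame in seconds from the first frame."""
        return np.arange(len(self)) * self.dt_s


@dataclass
class Roi:
    """A measurement region: axis-aligned rectangle or arbitrary binary mask.

    Rectangles store ``x0, y0, width, height`` with half-open extent;
    mask ROIs store a boolean grid the size of the source frame. Use the
    :meth:`rectangle` / :meth:`from_mask` constructors.
    """

    kind: str
    x0: int = 0
    y0: int = 0
    width: int = 0
    height: int = 0
    mask: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def rectangle(cls, x0: int, y0: int, width: int, height: int) -> "Roi":
        if width < 1 or height < 1:
            raise ValueError("rectangle ROI must have positive width and height")
        return cls(kind="rect", x0=int(x0), y0=int(y0), width=int(width), height=int(height))

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "Roi":
        mask = np.asarray(mask).astype(bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not mask.any():
            raise ValueError("empty-mask ROI (area must be >= 1)")
        return cls(kind="mask", mask=mask)

    @property
    def area_px(self) -> int:
        if self.kind == "rect":
            return self.width * self.height
        return int(self.mask.sum())

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of this ROI on a frame of the given (H, W) shape."""
        if self.kind == "mask":
            if self.mask.shape != tuple(shape):
                raise ValueError(
                    f"mask ROI shape {self.mask.shape} does not match frame shape {tuple(shape)}"
                )
            return self.mask
        m = np.zeros(shape, dtype=bool)
        m[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width] = True
        return m

    def within(self, shape: tuple[int, int]) -> bool:
        """True if the ROI lies entirely within a frame of the given shape."""
        h, w = shape
        if self.kind == "rect":
            return (
                0 <= self.x0
                and 0 <= self.y0
                and self.x0 + self.width <= w
                and self.y0 + self.height <= h
            )
        return self.mask.shape == (h, w)

    def pixels(self, frame: np.ndarray) -> np.ndarray:
        """1-D array of the frame's pixel values inside the ROI."""
        frame = np.asarray(frame)
        if not self.within(frame.shape):
            raise ValueError("ROI outside frame bounds")
        if self.kind == "rect":
            return frame[
                self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width
            ].ravel()
        return frame[self.mask]

    def contains(self, other: "Roi", shape: tuple[int, int]) -> bool:
        """True if this ROI is a superset of ``other`` on the given frame shape."""
        mine = self.to_mask(shape)
        theirs = other.to_mask(shape)
        return bool(np.all(mine | ~theirs))


# ---------------------------------------------------------------------------
# projections and intensity sums
# ---------------------------------------------------------------------------


def _stack_data(stack: "ZStack | np.ndarray") -> np.ndarray:
    data = stack.data if isinstance(stack, ZStack) else np.asarray(stack)
    if data.ndim != 3 or data.shape[0] < 1:
        raise ValueError("empty stack")
    return data


def max_project(stack: "ZStack | np.ndarray") -> np.ndarray:
    """Maximum-intensity z-projection: per-pixel maximum across slices."""
    return _stack_data(stack).max(axis=0)


def sum_project(stack: "ZStack | np.ndarray") -> np.ndarray:
    """Sum z-projection ("SUMstack"): per-pixel sum across slices.

    The accumulator is widened (int64 / float64), so the output may
    exceed the input bit depth; values are never clipped.
    """
    data = _stack_data(stack)
    acc = np.int64 if np.issubdtype(data.dtype, np.integer) else np.float64
    return data.sum(axis=0, dtype=acc)


def total_intensity(frame: np.ndarray, roi: Roi) -> float:
    """Sum of pixel values inside ``roi``. Additive over disjoint ROIs."""
    return float(roi.pixels(frame).sum(dtype=np.float64))


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

_KNOWN_AXES = set("TZCYX")


def read_series(
    path,
    axes: str = "TZYX",
    channel: int | None = None,
    dt_s: float = 10.0,
    pixel_size_um: float = 0.1,
    z_step_um: float = 0.8,
    channel_label: str = "",
) -> ImageSeries:
    """Read a multi-page TIFF into an :class:`ImageSeries`.

    ``axes`` declares the dimension order of the stored array using the
    letters T (time), Z, C (channel), Y, X — e.g. ``"TZCYX"`` or
    ``"TYX"``. If the file holds multiple channels, ``channel`` selects
    which one to return.
    """
    for ax in axes:
        if ax not in _KNOWN_AXES:
            raise ValueError(f"unrecognized dimension-order axis {ax!r} in {axes!r}")
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate axis in dimension order {axes!r}")
    if "Y" not in axes or "X" not in axes:
        raise ValueError("dimension order must include Y and X")

    data = tifffile.imread(path)
    if data.ndim != len(axes):
        raise ValueError(
            f"file has {data.ndim} dimensions but dimension order {axes!r} declares {len(axes)}"
        )

    # normalise to (T, Z, C, Y, X), inserting singleton axes as needed
    order = "TZCYX"
    for ax in order:
        if ax not in axes:
            data = np.expand_dims(data, axis=0)
            axes = ax + axes
    data = np.transpose(data, [axes.index(ax) for ax in order])

    n_channels = data.shape[2]
    if n_channels > 1:
        if channel is None:
            raise ValueError(
                f"file has {n_channels} channels; pass channel= to select one"
            )
        data = data[:, :, channel]
    else:
        data = data[:, :, 0]

    stacks = [ZStack(data[t], z_step_um=z_step_um) for t in range(data.shape[0])]
    return ImageSeries(
        stacks, dt_s=dt_s, pixel_size_um=pixel_size_um, channel=channel_label
    )


def write_series(series: ImageSeries, path) -> None:
    """Write an :class:`ImageSeries` as a multi-page TIFF with TZYX axes.

    The round trip through :func:`read_series` (with ``axes="TZYX"``)
    is bit-exact for integer data.
    """
    data = np.stack([st.data for st in series.stacks])
    tifffile.imwrite(path, data, photometric="minisblack", metadata={"axes": "TZYX"})
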