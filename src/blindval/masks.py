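"""Binary segmentation masks, Dice overlap, and summaries of DSC collections.

A mask is a binary raster: the foreground is the segmented region (e.g.
dense tissue on a mammogram), everything else background.  Agreement
between two sources that segmented the same image is measured with the
Dice similarity coefficient DSC = 2|A∩B| / (|A| + |B|), the standard
overlap index for segmentation evaluation, in [0, 1].

Collections of per-image DSC values are summarised as mean ± sd with a
Student-t confidence interval on the mean (t with n−1 df; the normal
approximation is visibly off for strata of a few dozen images).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy import stats

from .errors import AnalysisError, ImageIdMismatchError, MaskIOError, ShapeMismatchError

__all__ = [
    "BinaryMask",
    "DscSummary",
    "dice",
    "closest_mean_dsc",
    "mean_ci_t",
    "summarize_dsc",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class BinaryMask:
    """One source's binary segmentation of one image.

    ``data`` is a boolean array of shape (height, width); True pixels are
    foreground.  ``image_id`` and ``source_id`` are opaque identifiers
    (e.g. "img007" and "L1" / "L2" / "model").
    """

    image_id: str
    source_id: str
    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=bool)
        if arr.ndim != 2 or arr.size == 0:
            raise MaskIOError(
                f"mask for image {self.image_id!r} must be a non-empty 2-D raster"
            )
        object.__setattr__(self, "data", arr)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def area(self) -> int:
        """Number of foreground pixels."""
        return int(self.data.sum())

    @property
    def foreground(self) -> set[tuple[int, int]]:
        """Foreground pixel coordinates as (x, y) pairs."""
        ys, xs = np.nonzero(self.data)
        return set(zip(xs.tolist(), ys.tolist()))

    @classmethod
    def from_coords(
        cls,
        image_id: str,
        source_id: str,
        width: int,
        height: int,
        foreground: Iterable[tuple[int, int]],
    ) -> "BinaryMask":
        data = np.zeros((height, width), dtype=bool)
        for x, y in foreground:
            if not (0 <= x < width and 0 <= y < height):
                raise MaskIOError(f"foreground pixel ({x}, {y}) out of bounds")
            data[y, x] = True
        return cls(image_id, source_id, data)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) between two masks.

    Both masks must cover the same image at the same raster size.  Two
    empty masks score 1.0: two raters agreeing that there is no target
    region is perfect agreement.
    """
    if a.image_id != b.image_id:
        raise ImageIdMismatchError(
            f"cannot compare masks of different images: {a.image_id!r} vs {b.image_id!r}"
        )
    if a.data.shape != b.data.shape:
        raise ShapeMismatchError(
            f"mask shapes differ for image {a.image_id!r}: "
            f"{a.data.shape} vs {b.data.shape}"
        )
    denom = a.area + b.area
    if denom == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / denom


def closest_mean_dsc(pairs: Sequence[tuple[float, float]]) -> float:
    """Mean over images of the larger of two per-image DSC values.

    Used to score a model against the *closer* of two human annotators:
    for each image take max(DSC vs annotator 1, DSC vs annotator 2),
    then average over images.
    """
    if len(pairs) == 0:
        raise AnalysisError("closest_mean_dsc requires at least one pair")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise AnalysisError("pairs must be a sequence of (dsc1, dsc2) tuples")
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise AnalysisError("DSC values must lie in [0, 1]")
    return float(arr.max(axis=1).mean())


def mean_ci_t(mean: float, sd: float, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval for a mean: mean ± t_{1−α/2, n−1}·sd/√n."""
    if n < 2:
        raise AnalysisError(f"t-interval requires n >= 2, got n={n}")
    if sd < 0:
        raise AnalysisError("sd must be non-negative")
    if not 0.0 < conf_level < 1.0:
        raise AnalysisError("conf_level must lie in (0, 1)")
    t = stats.t.ppf(1.0 - (1.0 - conf_level) / 2.0, df=n - 1)
    half = t * sd / math.sqrt(n)
    return (mean - half, mean + half)


@dataclass(frozen=True)
class DscSummary:
    """Mean ± sd of n per-image DSC values with a t-interval on the mean.

    ``ci_low``/``ci_high`` are None when n < 2 (no spread estimate);
    callers should surface that as a flagged, CI-less summary.
    """

    n: int
    mean: float
    sd: float
    ci_low: float | None
    ci_high: float | None
    conf_level: float = 0.95


def summarize_dsc(values: Sequence[float], conf_level: float = 0.95) -> DscSummary:
    """Summarise a collection of DSC values (sample sd, n−1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise AnalysisError("cannot summarise an empty DSC collection")
    mean = float(arr.mean())
    if arr.size < 2:
        return DscSummary(n=1, mean=mean, sd=float("nan"), ci_low=None,
                          ci_high=None, conf_level=conf_level)
    sd = float(arr.std(ddof=1))
    lo, hi = mean_ci_t(mean, sd, arr.size, conf_level)
    return DscSummary(n=int(arr.size), mean=mean, sd=sd, ci_low=lo, ci_high=hi,
                      conf_level=conf_level)


def read_mask(path: str | Path, image_id: str = "", source_id: str = "") -> BinaryMask:
    """Read a raster mask file; any strictly positive pixel is foreground.

    Single-channel rasters are read directly; multi-channel content is
    binarized as "any channel positive".  Identifiers default to empty
    strings when the caller tracks them externally (e.g. via a manifest).
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except (OSError, ValueError, Image.DecompressionBombError) as exc:
        raise MaskIOError(f"cannot read mask file {path}: {exc}") from exc
    if arr.size == 0:
        raise MaskIOError(f"mask file {path} has zero-size raster")
    fg = arr > 0
    if fg.ndim == 3:
        fg = fg.any(axis=-1)
    if fg.ndim != 2:
        raise MaskIOError(f"mask file {path} is not a 2-D raster")
    return BinaryMask(image_id=image_id or path.stem, source_id=source_id, data=fg)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a single-channel PNG (foreground = 255)."""
    path = Path(path)
    img = Image.fromarray(mask.data.astype(np.uint8) * 255, mode="L")
    img.save(path)
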