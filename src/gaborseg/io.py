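"""Raster and model I/O.

Reads fundus photographs and binary vessel masks from common 8-bit raster
formats (PNG, TIFF, PPM, GIF), writes them back losslessly, serializes
trained classifiers to a versioned JSON format, and walks a DRIVE-style
directory layout (``images/``, ``1st_manual/``, ``mask/`` siblings paired by
numeric filename prefix).

Coordinate convention throughout the package: row-major, 0-based, pixel
``(r, c)`` = (row, column), origin at the top-left corner.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "FundusImage",
    "VesselMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "save_model",
    "load_model",
    "walk_drive_layout",
]

MODEL_FORMAT_VERSION = 1

_RASTER_SUFFIXES = {".png", ".tif", ".tiff", ".ppm", ".gif"}


@dataclass
class FundusImage:
    """An RGB fundus photograph with an optional circular field-of-view mask.

    ``pixels`` is an ``H×W×3`` uint8 array in R,G,B channel order.
    ``fov_mask`` is an ``H×W`` boolean array, True inside the field of view;
    when no mask file accompanies the image it is all-True.
    """

    pixels: np.ndarray
    fov_mask: np.ndarray = None  # type: ignore[assignment]
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"FundusImage requires an H×W×3 raster, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape[:2]
        if h < 16 or w < 16:
            raise ValueError(f"image too small: {h}×{w}, minimum is 16×16")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values outside the 8-bit range")
            self.pixels = self.pixels.astype(np.uint8)
        if self.fov_mask is None:
            self.fov_mask = np.ones((h, w), dtype=bool)
        else:
            self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
            if self.fov_mask.shape != (h, w):
                raise ValueError(
                    f"fov_mask shape {self.fov_mask.shape} does not match image {(h, w)}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class VesselMask:
    """Binary vessel ground truth; True marks a vessel pixel."""

    mask: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.mask.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def read_image(path: str | Path, fov_path: str | Path | None = None) -> FundusImage:
    """Read an RGB fundus image; optionally attach a field-of-view mask.

    Grayscale rasters are rejected: the feature extractor needs all three
    color channels. GIF (and palette) inputs are converted to RGB, which is
    how DRIVE ships its mask files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with Image.open(path) as im:
        if im.mode == "P":
            im = im.convert("RGB")
        arr = np.asarray(im)
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise ValueError(
            f"{path}: expected a 3-channel RGB image, got 1 channel (grayscale)"
        )
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        nchan = arr.shape[2] if arr.ndim == 3 else 1
        raise ValueError(f"{path}: expected a 3-channel RGB image, got {nchan} channels")
    arr = arr[:, :, :3]
    fov = None
    if fov_path is not None:
        fov = read_mask(fov_path, shape=arr.shape[:2]).mask
    return FundusImage(pixels=arr, fov_mask=fov, id=path.stem)


def write_image(img: FundusImage, path: str | Path) -> None:
    """Write the RGB raster to ``path`` (format from the suffix); lossless for PNG/TIFF/PPM."""
    Image.fromarray(img.pixels, mode="RGB").save(Path(path))


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> VesselMask:
    """Read a binary mask from any grayscale raster.

    Binarization rule: value > 0 ⇒ True. This handles both the {0,1} and
    {0,255} annotation dialects found in DRIVE-style ground truth.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(
            f"mask shape {arr.shape} does not match expected shape {tuple(shape)}"
        )
    return VesselMask(mask=arr > 0, id=path.stem)


def write_mask(mask: VesselMask | np.ndarray, path: str | Path) -> None:
    arr = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, dtype=bool)
    Image.fromarray((arr.astype(np.uint8)) * 255, mode="L").save(Path(path))


# ---------------------------------------------------------------------------
# Model serialization: self-describing, versioned, non-executable JSON.

def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _from_jsonable(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj["dtype"])
        return {k: _from_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_from_jsonable(v) for v in obj]
    return obj


def save_model(model, path: str | Path) -> None:
    """Serialize a trained classifier (QG, KNN or MLP) to versioned JSON."""
    from . import classifiers  # local import to avoid a cycle

    state = classifiers.model_state(model)
    payload = {
        "format": "gaborseg-model",
        "format_version": MODEL_FORMAT_VERSION,
        "model_type": state.pop("model_type"),
        "state": _to_jsonable(state),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    """Load a classifier saved by :func:`save_model`.

    ``load(save(m))`` predicts bit-identically to ``m``: arrays round-trip
    through decimal repr at full precision via ``tolist``.
    """
    from . import classifiers

    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "gaborseg-model":
        raise ValueError(f"{path} is not a gaborseg model file")
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model version {version!r} (this build reads version "
            f"{MODEL_FORMAT_VERSION})"
        )
    state = _from_jsonable(payload["state"])
    return classifiers.model_from_state(payload["model_type"], state)


# ---------------------------------------------------------------------------
# DRIVE-style directory layout


@dataclass
class DrivePair:
    image_path: Path
    truth_path: Path
    fov_path: Path | None = None
    key: str = ""


def _numeric_prefix(p: Path) -> str | None:
    m = re.match(r"(\d+)", p.stem)
    return m.group(1).lstrip("0") or "0" if m else None


def walk_drive_layout(root: str | Path) -> list[DrivePair]:
    """Pair files in ``root/images``, ``root/1st_manual`` and ``root/mask``
    by shared numeric filename prefix; the FOV mask directory is optional."""
    root = Path(root)
    img_dir = root / "images"
    truth_dir = root / "1st_manual"
    if not truth_dir.exists():
        truth_dir = root / "masks"  # phantom benchmark dialect
    fov_dir = root / "mask"
    if not img_dir.exists() or not truth_dir.exists():
        raise FileNotFoundError(
            f"{root} lacks the expected images/ and 1st_manual/ (or masks/) directories"
        )

    def index(d: Path) -> dict[str, Path]:
        out: dict[str, Path] = {}
        for p in sorted(d.iterdir()):
            if p.suffix.lower() in _RASTER_SUFFIXES:
                k = _numeric_prefix(p)
                if k is not None:
                    out.setdefault(k, p)
        return out

    imgs, truths = index(img_dir), index(truth_dir)
    fovs = index(fov_dir) if fov_dir.exists() else {}
    pairs = []
    for k in sorted(imgs, key=lambda s: (len(s), s)):
        if k in truths:
            pairs.append(
                DrivePair(image_path=imgs[k], truth_path=truths[k],
                          fov_path=fovs.get(k), key=k)
            )
    return pairs
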