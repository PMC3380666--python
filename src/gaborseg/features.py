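"""Per-pixel feature vectors: Gabor scale-maxima plus windowed L*u*v* color.

The shipped 15-dimensional layout concatenates, for each pixel:

* the 4 maximum-over-orientation Gabor responses (one per scale σ = 3,5,7,9),
* the 9 L* (lightness) values of the 3×3 window centred on the pixel, in
  row-major window order,
* the u*, v* chrominance of the centre pixel,

giving 4 + 9 + 2 = 15 features. The layout is configurable (window size,
number of Gabor scales, whether chrominance is windowed too). Color is CIE
1976 L*u*v* under sRGB primaries and D65 white — a space that separates
luminance from chrominance, which suits vessel/background discrimination.

All classifiers are scale-sensitive, so features are z-scored column-wise
with statistics fitted on the training partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

__all__ = ["FeatureLayout", "PixelFeatureMatrix", "rgb_to_luv",
           "assemble_features", "standardize", "destandardize",
           "features_to_frame", "frame_to_features"]


@dataclass(frozen=True)
class FeatureLayout:
    """Composition of the per-pixel feature vector.

    n_gabor        : number of Gabor maximum-response features (one per scale)
    window         : odd side length of the color window (3 ⇒ 3×3)
    chroma_windowed: if True all window u*,v* values enter (full Luv window);
                     default False keeps chrominance per-pixel.
    """

    n_gabor: int = 4
    window: int = 3
    chroma_windowed: bool = False

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if self.n_gabor < 0:
            raise ValueError("n_gabor must be nonnegative")

    @property
    def dim(self) -> int:
        w2 = self.window**2
        return self.n_gabor + (3 * w2 if self.chroma_windowed else w2 + 2)


@dataclass
class PixelFeatureMatrix:
    """N×D feature matrix with pixel provenance.

    standardization is either the string ``"raw"`` or a ``(mean, sd)`` pair
    of length-D arrays (the training-set statistics the matrix was z-scored
    with).
    """

    features: np.ndarray
    coords: np.ndarray            # N×2 int (row, col)
    image_ids: np.ndarray         # N object/str
    layout: FeatureLayout | None = field(default_factory=FeatureLayout)
    standardization: object = "raw"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        self.image_ids = np.asarray(self.image_ids)
        n = self.features.shape[0]
        if self.features.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got {self.features.shape}")
        # layout=None leaves the dimensionality unconstrained (free-form matrices)
        if self.layout is not None and self.features.shape[1] != self.layout.dim:
            raise ValueError(
                f"feature matrix is {self.features.shape}, layout dimensionality "
                f"is {self.layout.dim}"
            )
        if self.coords.shape != (n, 2) or self.image_ids.shape[0] != n:
            raise ValueError("coords/image_ids length mismatch with features")

    @property
    def n(self) -> int:
        return self.features.shape[0]


def rgb_to_luv(img) -> np.ndarray:
    """Convert an 8-bit RGB image to CIE 1976 L*u*v* (sRGB primaries, D65 white).

    Returns an H×W×3 float map with L* in [0, 100]; black maps to (0, 0, 0).
    """
    pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img)
    return _skcolor.rgb2luv(pixels.astype(np.uint8))


def assemble_features(stack, luv: np.ndarray, pixels, layout: FeatureLayout | None = None,
                      image_id: str = "") -> PixelFeatureMatrix:
    """Build the feature row for each requested pixel.

    ``stack`` is a :class:`~gaborseg.gabor.ResponseStack`; its first
    ``layout.n_gabor`` scale maxima are sampled at each pixel. The Luv map
    is reflect-padded so border pixels are classifiable. Row order follows
    the input pixel order exactly.
    """
    layout = layout or FeatureLayout()
    pixels = np.atleast_2d(np.asarray(pixels, dtype=int))
    max_maps = stack.max_maps
    h, w = luv.shape[:2]
    if max_maps.shape[0] < layout.n_gabor:
        raise ValueError(
            f"layout wants {layout.n_gabor} Gabor features but the response "
            f"stack has {max_maps.shape[0]} scales"
        )
    bad = (pixels[:, 0] < 0) | (pixels[:, 0] >= h) | (pixels[:, 1] < 0) | (pixels[:, 1] >= w)
    if bad.any():
        r, c = pixels[np.argmax(bad)]
        raise IndexError(f"pixel ({r}, {c}) outside the {h}×{w} image")

    half = layout.window // 2
    luv_pad = np.pad(luv, ((half, half), (half, half), (0, 0)), mode="reflect")
    rows, cols = pixels[:, 0], pixels[:, 1]

    parts = [max_maps[s][rows, cols] for s in range(layout.n_gabor)]
    # window offsets in row-major order
    offs = [(dr, dc) for dr in range(layout.window) for dc in range(layout.window)]
    lw = [luv_pad[rows + dr, cols + dc, 0] for dr, dc in offs]
    parts.extend(lw)
    if layout.chroma_windowed:
        for ch in (1, 2):
            parts.extend(luv_pad[rows + dr, cols + dc, ch] for dr, dc in offs)
    else:
        parts.append(luv[rows, cols, 1])
        parts.append(luv[rows, cols, 2])
    features = np.column_stack(parts)
    ids = np.full(pixels.shape[0], image_id, dtype=object)
    return PixelFeatureMatrix(features=features, coords=pixels, image_ids=ids, layout=layout)


def concat(matrices: list[PixelFeatureMatrix]) -> PixelFeatureMatrix:
    """Stack feature matrices from several images (identical layouts)."""
    if not matrices:
        raise ValueError("no feature matrices to concatenate")
    layout = matrices[0].layout
    if any(m.layout != layout for m in matrices):
        raise ValueError("feature layouts differ across matrices")
    return PixelFeatureMatrix(
        features=np.vstack([m.features for m in matrices]),
        coords=np.vstack([m.coords for m in matrices]),
        image_ids=np.concatenate([m.image_ids for m in matrices]),
        layout=layout,
    )


def standardize(fm: PixelFeatureMatrix, stats="fit") -> tuple[PixelFeatureMatrix, tuple]:
    """Z-score every feature column.

    ``stats="fit"`` estimates per-column (mean, sd) from ``fm`` itself —
    use this on the training partition only — and returns them for reuse on
    validation/test partitions. A constant column gets sd treated as 1 (with
    a warning) so it passes through centred but unscaled.
    """
    if isinstance(stats, str) and stats == "fit":
        mean = fm.features.mean(axis=0)
        sd = fm.features.std(axis=0, ddof=0)
        if np.any(sd == 0):
            warnings.warn("constant feature column(s); sd treated as 1", stacklevel=2)
            sd = np.where(sd == 0, 1.0, sd)
    else:
        mean, sd = (np.asarray(a, dtype=float) for a in stats)
        if mean.shape != (fm.features.shape[1],) or sd.shape != mean.shape:
            raise ValueError(
                f"standardization stats of length {mean.shape[0]} do not match "
                f"feature dimensionality {fm.features.shape[1]}"
            )
    out = replace_features(fm, (fm.features - mean) / sd)
    out.standardization = (mean.copy(), sd.copy())
    return out, (mean, sd)


def destandardize(fm: PixelFeatureMatrix) -> PixelFeatureMatrix:
    """Invert :func:`standardize` using the matrix's stored statistics."""
    if isinstance(fm.standardization, str):
        raise ValueError("matrix is not standardized")
    mean, sd = fm.standardization
    out = replace_features(fm, fm.features * sd + mean)
    out.standardization = "raw"
    return out


def replace_features(fm: PixelFeatureMatrix, features: np.ndarray) -> PixelFeatureMatrix:
    return PixelFeatureMatrix(
        features=features, coords=fm.coords.copy(), image_ids=fm.image_ids.copy(),
        layout=fm.layout, standardization=fm.standardization,
    )


# --- CSV interchange -------------------------------------------------------

def features_to_frame(fm: PixelFeatureMatrix, labels=None):
    """Feature matrix as a pandas DataFrame: image_id, row, col, f1..fD[, label]."""
    import pandas as pd

    d = fm.features.shape[1]
    data = {"image_id": fm.image_ids, "row": fm.coords[:, 0], "col": fm.coords[:, 1]}
    for j in range(d):
        data[f"f{j + 1}"] = fm.features[:, j]
    if labels is not None:
        data["label"] = np.asarray(labels, dtype=int)
    return pd.DataFrame(data)


def frame_to_features(df, layout: FeatureLayout | None = None) -> tuple[PixelFeatureMatrix, np.ndarray | None]:
    layout = layout or FeatureLayout()
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    fcols.sort(key=lambda c: int(c[1:]))
    fm = PixelFeatureMatrix(
        features=df[fcols].to_numpy(dtype=float),
        coords=df[["row", "col"]].to_numpy(dtype=int),
        image_ids=df["image_id"].to_numpy(dtype=object),
        layout=layout,
    )
    labels = df["label"].to_numpy(dtype=int) if "label" in df.columns else None
    return fm, labels
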