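"""Per-tile histomic feature vectors and feature-wise scaling.

Every tissue tile is mapped to a fixed-length feature vector by a pluggable
extractor.  Two deterministic extractors ship with the package:

``texture`` (d=64)
    Hand-crafted color/texture statistics (documented on
    :class:`TextureFeaturizer`).  No trained weights; drives the test suite.

``cnn512`` (d=512)
    A fixed-weight random-convolution network whose global-average-pooling
    output has 512 channels, matching the dimensionality of the deep-learning
    feature vector produced by a VGG19-style backbone's GAP layer.  Weights
    are He-initialized from a frozen seed, so the extractor is deterministic
    and download-free.  A fine-tuned pathology CNN can be registered as a
    drop-in replacement via :func:`register_extractor`.

Before clustering, feature columns are z-scored with the population standard
deviation (:func:`scale_features`); constant columns are mapped to zeros
rather than dropped so feature indices stay stable for activation mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .slide_io import Tile, TileGrid

__all__ = [
    "ExtractorSpec",
    "FeatureMatrix",
    "TextureFeaturizer",
    "ConvNetFeaturizer",
    "FeatureScaler",
    "register_extractor",
    "get_extractor",
    "texture_extractor",
    "extract_features",
    "scale_features",
]

_GRAY = np.array([0.2125, 0.7154, 0.0721])


class ExtractorContractError(RuntimeError):
    """An extractor returned a vector that violates its declared contract."""


@dataclass(frozen=True)
class ExtractorSpec:
    extractor_id: str
    dim: int
    deterministic: bool
    description: str = ""

    def __post_init__(self) -> None:
        if self.dim < 8:
            raise ValueError("extractor dim must be >= 8")


@dataclass
class FeatureMatrix:
    """Tiles x d matrix of histomic feature values for one slide."""

    slide_id: str
    tile_ids: list[str]
    values: np.ndarray = field(repr=False)
    extractor: ExtractorSpec
    scaled: bool = False
    scaling_stats: tuple[np.ndarray, np.ndarray] | None = None  # (mean, pop. SD)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.tile_ids):
            raise ValueError("values must be (n_tiles, d) matching tile_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_tiles(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=[f"f{i}" for i in range(self.dim)])
        df.insert(0, "tile_id", self.tile_ids)
        return df


def _validate_tile(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[-1] != 3 or pixels.dtype != np.uint8:
        raise ExtractorContractError("tile must be an RGB 8-bit raster")
    if pixels.shape[0] != pixels.shape[1]:
        raise ExtractorContractError("tile must be square")
    return pixels


def _local_variance(gray: np.ndarray, size: int) -> np.ndarray:
    m = ndimage.uniform_filter(gray, size=size)
    m2 = ndimage.uniform_filter(gray * gray, size=size)
    return np.clip(m2 - m * m, 0.0, None)


def _blob_proxy(gray: np.ndarray, sigma: float) -> float:
    """Count of strict local intensity minima after smoothing, per pixel.

    Nuclei are darker than their surround, so each resolved nucleus
    contributes roughly one smoothed local minimum.
    """
    sm = ndimage.gaussian_filter(gray, sigma=sigma)
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_min = ndimage.minimum_filter(sm, footprint=footprint, mode="nearest")
    return float(np.count_nonzero(sm < neigh_min)) / gray.size


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    mu = float(x.mean())
    sd = float(x.std())
    if sd == 0.0:
        return mu, 0.0, 0.0, 0.0
    z = (x - mu) / sd
    return mu, sd, float((z**3).mean()), float((z**4).mean() - 3.0)


class TextureFeaturizer(BaseEstimator, TransformerMixin):
    """Deterministic 64-dim color/texture fingerprint of an RGB tile.

    Feature layout (all intensities on a 0-1 scale):

    ====== ==========================================================
    index  block
    ====== ==========================================================
    0-2    RGB channel means
    3-5    RGB channel SDs
    6-21   16-bin grayscale histogram (density-normalized)
    22-23  gradient-magnitude mean, SD (central differences)
    24-31  8-bin gradient-magnitude histogram over [0, 0.5]
    32-38  local variance, 3x3 window: mean, SD, q10, q25, q50, q75, q90
    39-45  local variance, 9x9 window: same statistics
    46-49  Laplacian-of-Gaussian response mean, SD at sigma 1 and 3
    50-51  HSV saturation mean, SD
    52-53  hue circular mean (cos, sin)
    54-55  HSV value mean, SD
    56     blob-count proxy at sigma 2 (local minima per pixel)
    57     edge density (fraction of pixels with gradient > 0.05)
    58-59  grayscale mean, SD
    60-61  grayscale skewness, excess kurtosis (0 on constant tiles)
    62     grayscale histogram entropy (nats)
    63     blob-count proxy at sigma 4
    ====== ==========================================================
    """

    DIM = 64

    def fit(self, X, y=None):  # stateless
        return self

    def transform(self, X) -> np.ndarray:
        """X: iterable of Tile or of HxWx3 uint8 arrays -> (n, 64) matrix."""
        rows = [self.transform_tile(x) for x in X]
        return np.vstack(rows) if rows else np.empty((0, self.DIM))

    def transform_tile(self, tile) -> np.ndarray:
        pixels = _validate_tile(tile.pixels if isinstance(tile, Tile) else tile)
        rgb = pixels.astype(np.float64) / 255.0
        gray = rgb @ _GRAY

        out = np.empty(self.DIM)
        out[0:3] = rgb.reshape(-1, 3).mean(axis=0)
        out[3:6] = rgb.reshape(-1, 3).std(axis=0)
        hist, _ = np.histogram(gray, bins=16, range=(0.0, 1.0), density=True)
        out[6:22] = hist / 16.0  # density * bin width -> probabilities

        gy, gx = np.gradient(gray)
        gmag = np.hypot(gx, gy)
        out[22], out[23] = gmag.mean(), gmag.std()
        ghist, _ = np.histogram(gmag, bins=8, range=(0.0, 0.5), density=False)
        out[24:32] = ghist / gmag.size

        q = (10, 25, 50, 75, 90)
        for j, size in enumerate((3, 9)):
            lv = _local_variance(gray, size)
            base = 32 + 7 * j
            out[base], out[base + 1] = lv.mean(), lv.std()
            out[base + 2 : base + 7] = np.percentile(lv, q)

        for j, sigma in enumerate((1.0, 3.0)):
            log = ndimage.gaussian_laplace(gray, sigma=sigma)
            out[46 + 2 * j] = log.mean()
            out[47 + 2 * j] = log.std()

        mx = rgb.max(axis=-1)
        mn = rgb.min(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
        out[50], out[51] = sat.mean(), sat.std()
        from skimage.color import rgb2hsv

        hue = rgb2hsv(pixels).reshape(-1, 3)[:, 0] * 2 * np.pi
        out[52], out[53] = np.cos(hue).mean(), np.sin(hue).mean()
        out[54], out[55] = mx.mean(), mx.std()

        out[56] = _blob_proxy(gray, sigma=2.0)
        out[57] = float(np.count_nonzero(gmag > 0.05)) / gmag.size
        g_mu, g_sd, g_skew, g_kurt = _moments(gray)
        out[58:62] = (g_mu, g_sd, g_skew, g_kurt)
        p = hist / 16.0
        p = p[p > 0]
        out[62] = float(-(p * np.log(p)).sum())
        out[63] = _blob_proxy(gray, sigma=4.0)
        return out


class ConvNetFeaturizer(BaseEstimator, TransformerMixin):
    """Fixed-weight random-convolution network with a 512-channel GAP output.

    Tiles are resized to ``input_size`` and passed through three conv/ReLU
    stages (3->32->128->512 channels, 3x3 kernels, 2x2 max-pooling between
    stages); the final global average pool yields the 512-dim vector.  The
    He-initialized weights come from a frozen seed, so identical pixels give
    identical vectors on every machine.  Untrained random convolutional
    features are a standing baseline for texture discrimination; a trained
    backbone can be swapped in through the extractor registry.
    """

    DIM = 512
    _WEIGHT_SEED = 20230512

    def __init__(self, input_size: int = 32):
        self.input_size = input_size

    def _weights(self):
        rng = np.random.default_rng(self._WEIGHT_SEED)
        dims = [(3, 32), (32, 128), (128, self.DIM)]
        ws = []
        for cin, cout in dims:
            fan_in = cin * 9
            ws.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, 3, 3)))
        return ws

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        # x: (C, H, W); w: (Cout, C, 3, 3); valid convolution via im2col
        c, h, wid = x.shape
        oh, ow = h - 2, wid - 2
        cols = np.empty((c * 9, oh * ow))
        k = 0
        for dy in range(3):
            for dx in range(3):
                cols[k * c : (k + 1) * c] = x[:, dy : dy + oh, dx : dx + ow].reshape(c, -1)
                k += 1
        # cols rows are ordered offset-major, channel-minor: order weight rows likewise
        wm = np.concatenate(
            [w[:, :, dy, dx].T for dy in range(3) for dx in range(3)], axis=0
        )
        out = wm.T @ cols
        return out.reshape(w.shape[0], oh, ow)

    @staticmethod
    def _pool2(x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, : h2 * 2, : w2 * 2].reshape(c, h2, 2, w2, 2)
        return x.max(axis=(2, 4))

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        rows = [self.transform_tile(x) for x in X]
        return np.vstack(rows) if rows else np.empty((0, self.DIM))

    def transform_tile(self, tile) -> np.ndarray:
        from skimage.transform import resize

        pixels = _validate_tile(tile.pixels if isinstance(tile, Tile) else tile)
        img = resize(
            pixels.astype(np.float64) / 255.0,
            (self.input_size, self.input_size),
            anti_aliasing=True,
            preserve_range=True,
        )
        x = img.transpose(2, 0, 1)
        for i, w in enumerate(self._weights()):
            x = np.maximum(self._conv(x, w), 0.0)
            if i < 2:
                x = self._pool2(x)
        return x.mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# extractor registry

_REGISTRY: dict[str, tuple[ExtractorSpec, object]] = {}


def register_extractor(spec: ExtractorSpec, featurizer) -> None:
    """Register a featurizer (object with ``transform_tile``) under spec.extractor_id."""
    if spec.extractor_id in _REGISTRY and _REGISTRY[spec.extractor_id][0].dim != spec.dim:
        raise ValueError(f"extractor {spec.extractor_id!r} re-registered with a different dim")
    _REGISTRY[spec.extractor_id] = (spec, featurizer)


def get_extractor(extractor_id: str) -> tuple[ExtractorSpec, object]:
    try:
        return _REGISTRY[extractor_id]
    except KeyError:
        raise KeyError(
            f"unknown extractor {extractor_id!r}; registered: {sorted(_REGISTRY)}"
        ) from None


register_extractor(
    ExtractorSpec("texture", TextureFeaturizer.DIM, True,
                  "hand-crafted color/texture statistics"),
    TextureFeaturizer(),
)
register_extractor(
    ExtractorSpec("cnn512", ConvNetFeaturizer.DIM, True,
                  "fixed-weight random-convolution GAP features"),
    ConvNetFeaturizer(),
)


def texture_extractor(tile: Tile | np.ndarray) -> np.ndarray:
    """Built-in deterministic texture fingerprint of one tile (d=64)."""
    return TextureFeaturizer().transform_tile(tile)


def extract_features(grid: TileGrid, extractor: str | ExtractorSpec = "texture") -> FeatureMatrix:
    """One feature row per tissue tile; non-tissue tiles are excluded."""
    extractor_id = extractor if isinstance(extractor, str) else extractor.extractor_id
    spec, featurizer = get_extractor(extractor_id)
    tiles = grid.tissue_tiles()
    if not tiles:
        raise ValueError("grid has no tissue tiles")
    rows = []
    for tile in tiles:
        vec = np.asarray(featurizer.transform_tile(tile), dtype=np.float64)
        if vec.shape != (spec.dim,):
            raise ExtractorContractError(
                f"extractor {spec.extractor_id!r} returned shape {vec.shape}, "
                f"declared dim {spec.dim}"
            )
        rows.append(vec)
    return FeatureMatrix(
        slide_id=grid.slide.slide_id,
        tile_ids=[t.tile_id for t in tiles],
        values=np.vstack(rows),
        extractor=spec,
    )


class FeatureScaler(BaseEstimator, TransformerMixin):
    """Feature-wise z-scoring with population SD; constant columns -> zeros."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] < 2:
            raise ValueError("cannot scale a single tile")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)  # population SD (ddof=0)
        self.constant_mask_ = self.scale_ == 0.0
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        denom = np.where(self.constant_mask_, 1.0, self.scale_)
        Z = (X - self.mean_) / denom
        Z[:, self.constant_mask_] = 0.0
        return Z


def scale_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score each feature column (population SD) prior to clustering."""
    if fm.scaled:
        raise RuntimeError("feature matrix already scaled")
    scaler = FeatureScaler().fit(fm.values)
    if scaler.constant_mask_.any():
        warnings.warn(
            f"{int(scaler.constant_mask_.sum())} constant feature column(s) mapped to zeros",
            stacklevel=2,
        )
    return replace(
        fm,
        values=scaler.transform(fm.values),
        scaled=True,
        scaling_stats=(scaler.mean_.copy(), scaler.scale_.copy()),
    )
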