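"""Per-slice instance feature extraction with frozen extractors.

Each slice image is mapped to a fixed-length feature vector by a *frozen*
extractor — extraction is a pure function of (pixels, extractor weights) and
involves no training, no dropout and no augmentation.

Two extractors are exposed:

``light``
    A deterministic, seeded random-projection extractor (D_raw = 512) that
    needs no downloaded weights: each slice is summarized by an 8x8 grid of
    block means, standard deviations and smoothed minima (192 statistics),
    expressed as deviations from the scan's per-bag median statistics,
    then mapped through a fixed Gaussian projection with a ReLU and
    L2-normalized. Frozen random features preserve linear information about
    lesion contrast, which is all the trainable MIL head needs.

``vgg19``
    The transfer-learning scheme: per-block spatial average pooling of each
    VGG19 max-pool block output, per-block L2 normalization, concatenation
    (D_raw = 64+128+256+512+512 = 1472). Requires a deep-learning runtime
    with ImageNet weights; when unavailable an explicit error directs the
    caller to the ``light`` extractor.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .bags import ScanBag
from .errors import CacheVersionError, FeatureExtractorUnavailableError, ValidationError

__all__ = [
    "InstanceFeatureSet",
    "LightweightExtractor",
    "Vgg19Extractor",
    "get_extractor",
    "extract_features",
    "cache_features",
    "load_cached_features",
    "FeatureStore",
    "build_feature_store",
    "VGG19_BLOCK_WIDTHS",
    "vgg19_feature_dim",
]

FORMAT_VERSION = "1"

#: channel widths of the five VGG19 convolutional blocks
VGG19_BLOCK_WIDTHS = (64, 128, 256, 512, 512)


def vgg19_feature_dim() -> int:
    """Raw dimension of concatenated per-block pooled VGG19 features."""
    return int(sum(VGG19_BLOCK_WIDTHS))


@dataclass
class InstanceFeatureSet:
    """Per-slice feature vectors for one scan; row order = slice order."""

    scan_id: str
    matrix: np.ndarray  # (N, D_raw)
    extractor_id: str
    version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValidationError(
                f"feature matrix for {self.scan_id} must be (N>=1, D)"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError(f"non-finite features for scan {self.scan_id}")

    @property
    def n_instances(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])


def _grid_stats(img: np.ndarray, grid: int = 8, smooth_sigma: float = 2.0) -> np.ndarray:
    """Block means, standard deviations and smoothed minima on a grid partition.

    The third statistic is the block minimum of a Gaussian-smoothed copy of
    the slice: the lesions of interest are blob-like hypoattenuated (dark)
    regions, and a smoothed minimum is the classic blob response — averaging
    away per-pixel noise so that genuine dark blobs, not noise pixels, set
    the minimum.
    """
    from scipy.ndimage import gaussian_filter

    smoothed = gaussian_filter(np.asarray(img, dtype=np.float64), smooth_sigma)

    def blocks(a):
        return [
            c
            for r in np.array_split(a, grid, axis=0)
            for c in np.array_split(r, grid, axis=1)
        ]

    raw = blocks(img)
    stats = (
        [c.mean() for c in raw]
        + [c.std() for c in raw]
        + [c.min() for c in blocks(smoothed)]
    )
    return np.asarray(stats, dtype=np.float64)


class LightweightExtractor:
    """Seeded frozen random-projection extractor, D_raw = 512, no downloads.

    Slices are summarized by grid statistics (block means, SDs, and blob-
    sensitive smoothed minima), centered on the scan's per-slice median
    statistics (bag-context normalization: a slice is represented by how it
    deviates from its scan's typical slice), randomly projected, rectified
    and L2-normalized to norm sqrt(D). The bag-relative representation makes
    typical slices of every scan nearly identical, so only atypical
    (lesion-like) slices carry scan-discriminative signal — which both helps
    the weakly supervised head and anchors the attention mechanism on the
    slices that actually differ.
    """

    def __init__(self, dim: int = 512, grid: int = 8, seed: int = 2023):
        self.dim = dim
        self.grid = grid
        self.seed = seed
        rng = np.random.default_rng(seed)
        d_in = 3 * grid * grid
        self._W = rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, dim))
        self._b = rng.normal(0.0, 0.1, size=dim)

    @property
    def extractor_id(self) -> str:
        return f"light-{self.dim}-g{self.grid}-s{self.seed}"

    def extract(self, bag: ScanBag) -> InstanceFeatureSet:
        stats = np.stack([_grid_stats(s, self.grid) for s in bag.slices])
        # bag-context normalization: subtract the per-bag median of each
        # statistic so slices are represented by their deviation from the
        # scan's own typical slice; typical (clean) slices of every scan then
        # map to nearly the same point and only atypical slices carry
        # bag-discriminative signal
        stats = stats - np.median(stats, axis=0, keepdims=True)
        feats = np.maximum(stats @ self._W + self._b, 0.0)
        # L2-normalize to norm sqrt(D) (per-coordinate RMS ~ 1), mirroring the
        # per-block L2 normalization of the transfer path; keeps downstream
        # activations at unit scale regardless of image intensity range
        norms = np.linalg.norm(feats, axis=1, keepdims=True)
        feats = feats * (np.sqrt(self.dim) / np.maximum(norms, 1e-12))
        return InstanceFeatureSet(bag.scan_id, feats, self.extractor_id)


class Vgg19Extractor:
    """ImageNet-pretrained VGG19 multi-block pooled features (D_raw = 1472).

    Grayscale slices are replicated to 3 channels; each max-pool block output
    is spatially average-pooled, L2-normalized per block, and concatenated.
    Instantiation requires a deep-learning runtime with downloadable ImageNet
    weights; otherwise :class:`FeatureExtractorUnavailableError` is raised.
    """

    dim = vgg19_feature_dim()
    extractor_id = "vgg19-imagenet-blockpool"

    def __init__(self) -> None:
        self._backend = self._load_backend()

    @staticmethod
    def _load_backend():
        for mod in ("tensorflow", "torch"):
            try:
                return __import__(mod)
            except ImportError:
                continue
        raise FeatureExtractorUnavailableError(
            "the vgg19 extractor needs a deep-learning runtime (tensorflow or "
            "torch) with ImageNet weights, which is not available here; use "
            "the 'light' extractor instead (extractor='light')"
        )

    def extract(self, bag: ScanBag) -> InstanceFeatureSet:  # pragma: no cover
        raise FeatureExtractorUnavailableError(
            "vgg19 weight loading is not implemented for this runtime; "
            "use the 'light' extractor instead"
        )


def get_extractor(name: str, **kwargs):
    if name == "light":
        return LightweightExtractor(**kwargs)
    if name == "vgg19":
        return Vgg19Extractor(**kwargs)
    raise ValidationError(f"unknown extractor {name!r}; choose 'light' or 'vgg19'")


def extract_features(bag: ScanBag, extractor) -> InstanceFeatureSet:
    """Extract one feature vector per slice with a frozen extractor."""
    if isinstance(extractor, str):
        extractor = get_extractor(extractor)
    return extractor.extract(bag)


def cache_features(features: dict[str, InstanceFeatureSet] | InstanceFeatureSet, path):
    """Persist features as an .npz with a JSON sidecar recording provenance."""
    if isinstance(features, InstanceFeatureSet):
        features = {features.scan_id: features}
    ids = sorted(features)
    extractor_ids = {features[i].extractor_id for i in ids}
    versions = {features[i].version for i in ids}
    if len(extractor_ids) != 1 or len(versions) != 1:
        raise ValidationError("cannot cache features from mixed extractors")
    path = os.fspath(path)
    np.savez(path, **{i: features[i].matrix for i in ids})
    sidecar = {
        "extractor_id": extractor_ids.pop(),
        "version": versions.pop(),
        "scan_ids": ids,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_cached_features(path, expect_extractor_id: str | None = None):
    """Inverse of :func:`cache_features`; validates extractor identity."""
    path = os.fspath(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    if sidecar.get("version") != FORMAT_VERSION:
        raise CacheVersionError(
            f"feature cache version {sidecar.get('version')!r} != {FORMAT_VERSION!r}"
        )
    if expect_extractor_id is not None and sidecar["extractor_id"] != expect_extractor_id:
        raise CacheVersionError(
            f"cache was built with extractor {sidecar['extractor_id']!r}, "
            f"expected {expect_extractor_id!r}"
        )
    with np.load(path if path.endswith(".npz") else path + ".npz") as data:
        return {
            i: InstanceFeatureSet(i, data[i], sidecar["extractor_id"], sidecar["version"])
            for i in sidecar["scan_ids"]
        }


def build_feature_store(bags, extractor) -> "FeatureStore":
    """Extract features for every bag and wrap them in a :class:`FeatureStore`."""
    if isinstance(extractor, str):
        extractor = get_extractor(extractor)
    return FeatureStore({b.scan_id: extractor.extract(b) for b in bags})


class FeatureStore:
    """Mapping scan_id -> feature matrix with an access log.

    The log records every scan whose features were read, which lets tests
    verify that no held-out scan is touched during training.
    """

    def __init__(self, features: dict[str, InstanceFeatureSet]):
        self._features = dict(features)
        self.access_log: list[str] = []

    def __contains__(self, scan_id: str) -> bool:
        return scan_id in self._features

    def __len__(self) -> int:
        return len(self._features)

    def scan_ids(self) -> list[str]:
        return list(self._features)

    def get(self, scan_id: str) -> np.ndarray:
        if scan_id not in self._features:
            raise ValidationError(f"no cached features for scan {scan_id!r}")
        self.access_log.append(scan_id)
        return self._features[scan_id].matrix

    @property
    def dim(self) -> int:
        first = next(iter(self._features.values()))
        return first.dim
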