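"""Synthetic CT-like phantom scans with known slice-level ground truth.

Real low-dose CT screening cohorts with visual emphysema scores are rarely
public, so this module generates abstract lung phantoms that preserve the
*structure* the MIL pipeline relies on:

* bags of ordered axial slices with a scan-level binary label,
* the MIL rule (a scan is positive iff at least one slice carries a lesion),
* lesion slices concentrated at a configurable normalized axial depth
  (emulating the upper-lobe predominance of centrilobular emphysema), with a
  "panlobular-like" phenotype that instead spreads lesions across the lung,
* nuisance slice features (nodule-like, bronchial-like, distortion-like and
  ground-glass-like patterns) drawn independently of the scan label, so that
  attended-slice feature-prevalence analyses can be validated against known
  rates.

Lesions are rendered as hypoattenuated (dark) blobs inside a fixed two-ellipse
lung mask. Intensities are abstract, in [0, 1]; no Hounsfield calibration is
attempted because the downstream method never uses HU thresholds. The
``signal_effect`` parameter scales the lesion contrast in units of the slice
noise standard deviation; at 0 lesion and clean slices are indistinguishable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import stats

from .bags import ScanBag
from .errors import ConfigurationError

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "generate_phantoms",
    "render_volume",
    "write_phantom_set",
    "NUISANCE_FEATURES",
    "PHENOTYPES",
    "CONCENTRATED_PHENOTYPES",
]

NUISANCE_FEATURES = ("nodule", "bronchial", "distortion", "ground_glass")
PHENOTYPES = ("centrilobular", "panlobular", "paraseptal")
#: phenotypes whose lesions concentrate at the configured depth mode
CONCENTRATED_PHENOTYPES = ("centrilobular", "paraseptal")

_NOISE_SIGMA = 0.05  # slice noise sd; lesion contrast = signal_effect * sigma


@dataclass
class PhantomConfig:
    """Generation parameters for a synthetic phantom cohort.

    ``lesion_depth_mode``/``lesion_depth_spread`` set the peak and dispersion
    of a truncated normal on [0, 1] from which lesion depths are drawn for
    the concentrated phenotypes; panlobular-like scans draw uniformly.
    The default mode of 0.2 places lesions in the upper lung.
    """

    n_scans: int = 300
    positive_fraction: float = 0.5
    slices_per_scan: tuple[int, int] = (20, 60)
    lesion_depth_mode: float = 0.2
    lesion_depth_spread: float = 0.1
    lesion_fraction: float = 0.3
    signal_effect: float = 3.0
    nuisance_rates: dict = field(
        default_factory=lambda: {
            "nodule": 0.05,
            "bronchial": 0.10,
            "distortion": 0.08,
            "ground_glass": 0.15,
        }
    )
    phenotype_mix: dict = field(
        default_factory=lambda: {
            # roughly the 284/40/33 phenotype ratio of a screening cohort
            "centrilobular": 0.80,
            "panlobular": 0.11,
            "paraseptal": 0.09,
        }
    )
    slice_shape: tuple[int, int] = (64, 64)
    seed: int = 0

    def validate(self) -> None:
        if self.n_scans < 1:
            raise ConfigurationError("n_scans must be >= 1")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ConfigurationError("positive_fraction must lie in [0, 1]")
        if not 0.0 < self.lesion_fraction <= 1.0:
            raise ConfigurationError("lesion_fraction must lie in (0, 1]")
        if not 0.0 <= self.lesion_depth_mode <= 1.0:
            raise ConfigurationError("lesion_depth_mode must lie in [0, 1]")
        if self.lesion_depth_spread <= 0:
            raise ConfigurationError("lesion_depth_spread must be > 0")
        lo, hi = self.slices_per_scan
        if lo < 1 or hi < lo:
            raise ConfigurationError("slices_per_scan must be a valid (lo, hi) range")
        if self.signal_effect < 0:
            raise ConfigurationError("signal_effect must be >= 0")
        for name, p in self.nuisance_rates.items():
            if name not in NUISANCE_FEATURES:
                raise ConfigurationError(f"unknown nuisance feature {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"nuisance rate for {name!r} not in [0, 1]")
        mix = [self.phenotype_mix.get(p, 0.0) for p in PHENOTYPES]
        if any(m < 0 for m in mix) or not np.isclose(sum(mix), 1.0):
            raise ConfigurationError("phenotype_mix must be non-negative and sum to 1")


@dataclass
class GroundTruth:
    """Per-scan and per-slice truth for one generated phantom.

    The MIL rule holds by construction: ``scan_label`` is 1 iff at least one
    entry of ``slice_labels`` is 1.
    """

    scan_id: str
    scan_label: int
    slice_labels: np.ndarray  # (N,) in {0,1}
    nuisance_flags: dict  # feature name -> (N,) bool array
    phenotype: str
    render_seed: int

    @property
    def n_slices(self) -> int:
        return int(self.slice_labels.size)


def _truncnorm_depths(mode: float, spread: float, size: int, rng: np.random.Generator):
    a, b = (0.0 - mode) / spread, (1.0 - mode) / spread
    return stats.truncnorm.rvs(a, b, loc=mode, scale=spread, size=size, random_state=rng)


def _draw_truth(config: PhantomConfig, rng: np.random.Generator) -> Iterator[GroundTruth]:
    n_pos = int(np.round(config.n_scans * config.positive_fraction))
    labels = np.zeros(config.n_scans, dtype=int)
    labels[rng.choice(config.n_scans, size=n_pos, replace=False)] = 1
    mix = np.array([config.phenotype_mix.get(p, 0.0) for p in PHENOTYPES])
    lo, hi = config.slices_per_scan
    for i in range(config.n_scans):
        n = int(rng.integers(lo, hi + 1))
        slice_labels = np.zeros(n, dtype=int)
        phenotype = PHENOTYPES[rng.choice(len(PHENOTYPES), p=mix / mix.sum())]
        if labels[i] == 1:
            n_lesion = max(1, int(np.round(config.lesion_fraction * n)))
            if phenotype == "panlobular":
                depths = rng.uniform(0.0, 1.0, size=4 * n_lesion + 8)
            else:
                depths = _truncnorm_depths(
                    config.lesion_depth_mode,
                    config.lesion_depth_spread,
                    4 * n_lesion + 8,
                    rng,
                )
            idx = np.unique(np.round(depths * (n - 1)).astype(int))
            if idx.size > n_lesion:
                idx = rng.choice(idx, size=n_lesion, replace=False)
            # depth draws can collide on few slices; top up from remaining indices
            if idx.size < n_lesion:
                rest = np.setdiff1d(np.arange(n), idx)
                extra = rng.choice(rest, size=n_lesion - idx.size, replace=False)
                idx = np.concatenate([idx, extra])
            slice_labels[idx] = 1
        nuisance = {
            name: rng.random(n) < rate for name, rate in config.nuisance_rates.items()
        }
        yield GroundTruth(
            scan_id=f"phantom_{i:04d}",
            scan_label=int(labels[i]),
            slice_labels=slice_labels,
            nuisance_flags=nuisance,
            phenotype=phenotype,
            render_seed=int(rng.integers(0, 2**31 - 1)),
        )


def _lung_mask(shape: tuple[int, int]) -> np.ndarray:
    """Fixed two-ellipse lung mask (left and right lung fields)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, ry = h / 2.0, 0.34 * h
    masks = []
    for cx in (0.30 * w, 0.70 * w):
        rx = 0.16 * w
        masks.append(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0)
    return masks[0] | masks[1]


def _body_mask(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - w / 2.0) / (0.46 * w)) ** 2 + ((yy - h / 2.0) / (0.46 * h)) ** 2 <= 1.0


def _disc(shape, cy, cx, r) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _random_point_in(mask: np.ndarray, rng: np.random.Generator, margin: int = 3):
    ys, xs = np.nonzero(mask)
    keep = (
        (ys > margin)
        & (ys < mask.shape[0] - margin)
        & (xs > margin)
        & (xs < mask.shape[1] - margin)
    )
    ys, xs = ys[keep], xs[keep]
    j = int(rng.integers(len(ys)))
    return int(ys[j]), int(xs[j])


def _render_slice(
    shape: tuple[int, int],
    lesion: bool,
    flags: dict,
    signal_effect: float,
    rng: np.random.Generator,
) -> np.ndarray:
    lung = _lung_mask(shape)
    body = _body_mask(shape)
    img = np.full(shape, 0.05, dtype=np.float32)  # air
    img[body] = 0.70  # soft tissue
    img[lung] = 0.40  # aerated lung
    if lesion:
        # hypoattenuated blob: contrast scales with signal_effect (in noise sds)
        cy, cx = _random_point_in(lung, rng)
        r = rng.uniform(2.5, 5.0)
        img[_disc(shape, cy, cx, r) & lung] -= signal_effect * _NOISE_SIGMA
    if flags.get("nodule", False):
        cy, cx = _random_point_in(lung, rng)
        img[_disc(shape, cy, cx, rng.uniform(1.0, 2.0)) & lung] += 0.35
    if flags.get("bronchial", False):
        cy, cx = _random_point_in(lung, rng)
        outer = _disc(shape, cy, cx, rng.uniform(3.0, 4.5))
        inner = _disc(shape, cy, cx, rng.uniform(1.0, 2.0))
        img[(outer & ~inner) & lung] += 0.25
    if flags.get("distortion", False):
        # a few bright streaks across the lung field
        for _ in range(3):
            y0, x0 = _random_point_in(lung, rng)
            ang = rng.uniform(0, np.pi)
            t = np.arange(-6, 7)
            ys = np.clip(np.round(y0 + t * np.sin(ang)).astype(int), 0, shape[0] - 1)
            xs = np.clip(np.round(x0 + t * np.cos(ang)).astype(int), 0, shape[1] - 1)
            sel = lung[ys, xs]
            img[ys[sel], xs[sel]] += 0.20
    if flags.get("ground_glass", False):
        cy, cx = _random_point_in(lung, rng, margin=6)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        bump = 0.10 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 6.0**2)))
        img[lung] += bump[lung].astype(np.float32)
    img += rng.normal(0.0, _NOISE_SIGMA, size=shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


def render_volume(truth: GroundTruth, config: PhantomConfig) -> ScanBag:
    """Render the slices of one phantom from its ground truth.

    Deterministic given ``truth.render_seed``; identical truth yields
    bit-identical pixels.
    """
    rng = np.random.default_rng(truth.render_seed)
    flags_per_slice = [
        {name: bool(truth.nuisance_flags[name][j]) for name in truth.nuisance_flags}
        for j in range(truth.n_slices)
    ]
    slices = np.stack(
        [
            _render_slice(
                config.slice_shape,
                bool(truth.slice_labels[j]),
                flags_per_slice[j],
                config.signal_effect,
                rng,
            )
            for j in range(truth.n_slices)
        ]
    )
    return ScanBag(
        scan_id=truth.scan_id,
        slices=slices,
        label=truth.scan_label,
        metadata={"phenotype": truth.phenotype},
    )


def generate_phantoms(config: PhantomConfig) -> list[tuple[ScanBag, GroundTruth]]:
    """Generate a reproducible phantom cohort.

    Returns exactly ``config.n_scans`` (bag, truth) pairs. Positive scans
    carry at least one lesion slice, negative scans carry none, and lesion
    depths follow the configured mode/spread for the concentrated phenotypes
    (uniform across depth for panlobular-like scans).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = []
    for truth in _draw_truth(config, rng):
        out.append((render_volume(truth, config), truth))
    return out


def write_phantom_set(
    pairs: list[tuple[ScanBag, GroundTruth]],
    out_dir: str | os.PathLike,
) -> str:
    """Write phantoms as NIfTI volumes plus manifest and per-slice truth CSVs.

    Volumes are stored with an affine whose z step is negative so that array
    slice 0 is the most superior (lung-top) slice; readers that honor the
    affine recover the top-first order regardless of storage direction.
    Returns the manifest path.
    """
    import nibabel as nib
    import pandas as pd

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    affine = np.diag([1.0, 1.0, -1.0, 1.0])
    manifest_rows, slice_rows = [], []
    for bag, truth in pairs:
        fname = f"{bag.scan_id}.nii.gz"
        vol = np.transpose(bag.slices, (1, 2, 0))  # (H, W, N), slice axis last
        nib.save(nib.Nifti1Image(vol, affine), os.path.join(out_dir, fname))
        manifest_rows.append(
            {
                "scan_id": bag.scan_id,
                "path": fname,
                "label": bag.label,
                "phenotype": truth.phenotype,
                "n_slices": bag.n_slices,
            }
        )
        for j in range(truth.n_slices):
            row = {
                "scan_id": bag.scan_id,
                "slice_index": j,
                "slice_label": int(truth.slice_labels[j]),
            }
            row.update(
                {name: int(truth.nuisance_flags[name][j]) for name in NUISANCE_FEATURES}
            )
            slice_rows.append(row)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(slice_rows).to_csv(os.path.join(out_dir, "slices.csv"), index=False)
    return manifest_path
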