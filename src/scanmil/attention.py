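"""Attention-weight interpretability: depth profiles and attended-feature prevalence.

Attention weights are per-scan min–max scaled to [0, 1] and plotted against
normalized axial depth (0 = lung top, 1 = lung bottom). A least-squares
polynomial fitted to the pooled (depth, scaled weight) points of a group of
scans summarizes where the model looks; three influence metrics quantify it:

1. depth of maximum attention of the fit curve (% of lung depth),
2. weighted average of slice depths weighted by (raw) attention (%),
3. range of fit-curve attention values (%).

Separately, the top-k attended slices per scan are checked for the presence
of annotated imaging features, and their prevalence compared with the
whole-scan prevalence — which imaging findings the attention favors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "AttentionProfile",
    "InfluenceMetrics",
    "scale_attention",
    "fit_group_curve",
    "influence_metrics",
    "topk_prevalence",
]

logger = logging.getLogger(__name__)

DEFAULT_CURVE_DEGREE = 4
_GRID = 2001  # evaluation grid on [0, 1] for curve extrema


def scale_attention(a: Sequence[float]) -> np.ndarray:
    """Min–max scale attention weights to [0, 1].

    A constant vector (no spread) maps to the uninformative midpoint 0.5.
    Scaling is monotone, so slice rankings are preserved.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size < 1:
        raise ValidationError("attention must be a non-empty 1-D vector")
    if np.any(a < 0):
        raise ValidationError("attention weights must be non-negative")
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.full_like(a, 0.5)
    return (a - lo) / (hi - lo)


@dataclass
class AttentionProfile:
    """Per-scan attention as a function of normalized depth."""

    scan_id: str
    depths: np.ndarray
    attention: np.ndarray  # raw per-scan weights (sum to 1)
    group: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.attention = np.asarray(self.attention, dtype=float)
        if self.depths.shape != self.attention.shape:
            raise ValidationError(
                f"scan {self.scan_id}: depths and attention must align"
            )
        self.scaled = scale_attention(self.attention)


class FittedCurve:
    """Polynomial least-squares fit of scaled attention vs depth, on [0, 1]."""

    def __init__(self, coeffs: np.ndarray):
        self._poly = np.poly1d(coeffs)
        grid = np.linspace(0.0, 1.0, _GRID)
        vals = self._poly(grid)
        self.argmax_depth = float(grid[np.argmax(vals)])
        self.value_range = float(vals.max() - vals.min())

    def __call__(self, depth):
        return self._poly(np.asarray(depth, dtype=float))


def fit_group_curve(
    profiles: Iterable[AttentionProfile], degree: int = DEFAULT_CURVE_DEGREE
) -> FittedCurve:
    """Least-squares polynomial over the pooled (depth, scaled weight) points."""
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("need at least one attention profile")
    depths = np.concatenate([p.depths for p in profiles])
    scaled = np.concatenate([p.scaled for p in profiles])
    n_unique = len(np.unique(depths))
    if depths.size <= degree or n_unique <= degree:
        raise ValidationError(
            f"{depths.size} points at {n_unique} depths cannot support a "
            f"degree-{degree} fit"
        )
    return FittedCurve(np.polyfit(depths, scaled, degree))


@dataclass
class InfluenceMetrics:
    """Depth-influence summary of a group of scans, in % of lung depth."""

    max_attention_depth: float  # argmax of fit curve * 100
    weighted_avg_depth: float  # attention-weighted mean slice depth * 100
    attention_range: float  # (max - min) of fit curve on [0,1] * 100


def influence_metrics(
    curve: FittedCurve, profiles: Iterable[AttentionProfile]
) -> InfluenceMetrics:
    """The three influence metrics for a fitted group curve.

    The weighted average pools all slices of all profiles using the raw
    per-scan attention weights; it is invariant to uniform rescaling of the
    weights within a scan only when scans contribute equal total weight,
    which holds here because attention sums to one per scan.
    """
    profiles = list(profiles)
    depths = np.concatenate([p.depths for p in profiles])
    weights = np.concatenate([p.attention for p in profiles])
    total = weights.sum()
    if total <= 0:
        raise ValidationError("attention weights sum to zero")
    return InfluenceMetrics(
        max_attention_depth=100.0 * curve.argmax_depth,
        weighted_avg_depth=100.0 * float((depths * weights).sum() / total),
        attention_range=100.0 * curve.value_range,
    )


def topk_prevalence(
    attention: dict,
    feature_flags: dict,
    k_values: Sequence[int],
    feature_names: Optional[Sequence[str]] = None,
) -> dict:
    """Feature prevalence among each scan's top-k attended slices.

    Parameters
    ----------
    attention : dict
        scan_id -> per-slice attention weights.
    feature_flags : dict
        scan_id -> {feature name -> boolean per-slice array}.
    k_values : sequence of int
        Values of k; a k exceeding a scan's slice count is clipped to it
        (with a logged warning). Ties in attention break toward the lower
        slice index, so selections are deterministic.

    Returns
    -------
    dict with ``"whole_scan"`` (feature -> fraction of scans in which the
    feature appears on any slice) and ``"top_k"`` (k -> feature -> fraction
    of scans whose top-k attended slices contain the feature).
    """
    scan_ids = list(attention)
    if not scan_ids:
        raise ValidationError("no scans provided")
    if feature_names is None:
        feature_names = sorted(next(iter(feature_flags.values())))
    whole = {
        f: float(np.mean([bool(np.any(feature_flags[s][f])) for s in scan_ids]))
        for f in feature_names
    }
    top_k = {}
    for k in k_values:
        counts = {f: 0 for f in feature_names}
        for s in scan_ids:
            a = np.asarray(attention[s], dtype=float)
            kk = min(k, a.size)
            if kk < k:
                logger.warning(
                    "scan %s has only %d slices; clipping k=%d", s, a.size, k
                )
            # stable sort on -a: equal weights resolve to the lower slice index
            top = np.argsort(-a, kind="stable")[:kk]
            for f in feature_names:
                if np.any(np.asarray(feature_flags[s][f])[top]):
                    counts[f] += 1
        top_k[int(k)] = {f: counts[f] / len(scan_ids) for f in feature_names}
    return {"whole_scan": whole, "top_k": top_k}
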