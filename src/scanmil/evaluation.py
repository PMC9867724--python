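"""ROC/AUC evaluation and DeLong paired comparison across repeated splits.

The AUC is computed as the Mann–Whitney statistic with ties counted 1/2, and
its variance from the DeLong structural components (the per-positive and
per-negative placement values). Two models scored on the *same* cases are
compared with the paired DeLong z-test, which accounts for the covariance of
their structural components. Model comparisons over repeated splits are
aggregated by the median of the per-repeat p-values, with a Bonferroni
correction across the family of model pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import DegenerateComparisonError, ValidationError

__all__ = [
    "roc_auc",
    "delong_test",
    "aggregate_comparisons",
    "EvalReport",
    "build_report",
]


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValidationError("both classes must be present")
    rank_all = _midrank(np.concatenate([pos, neg]))
    v10 = (rank_all[:m] - _midrank(pos)) / n
    v01 = 1.0 - (rank_all[m:] - _midrank(neg)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores, labels):
    """AUC (midrank Mann–Whitney) with its DeLong variance.

    Returns ``(auc, variance)``.
    """
    auc, v10, v01 = _structural_components(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def delong_test(scores_a, scores_b, labels):
    """Two-sided paired DeLong test for AUC difference on identical cases.

    Returns ``(z, p)``. Raises :class:`DegenerateComparisonError` when the
    variance of the AUC difference is zero (e.g. identical score vectors).
    """
    labels = np.asarray(labels)
    auc_a, v10_a, v01_a = _structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _structural_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        raise DegenerateComparisonError(
            "zero variance of the AUC difference (identical or degenerate scores)"
        )
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def aggregate_comparisons(
    per_pair_p: dict, alpha: float = 0.05, correction: str = "bonferroni"
) -> dict:
    """Median p per model pair plus multiplicity-corrected significance flags.

    ``per_pair_p`` maps a pair key to its per-repeat p-values; all pairs must
    have the same number of repeats.
    """
    from statsmodels.stats.multitest import multipletests

    lengths = {len(v) for v in per_pair_p.values()}
    if len(lengths) > 1:
        raise ValidationError(f"mismatched repeat counts across pairs: {lengths}")
    pairs = list(per_pair_p)
    medians = np.array([float(np.median(per_pair_p[k])) for k in pairs])
    reject, _, _, _ = multipletests(medians, alpha=alpha, method=correction)
    return {
        pair: {"median_p": float(med), "significant": bool(rej)}
        for pair, med, rej in zip(pairs, medians, reject)
    }


@dataclass
class EvalReport:
    """Per-model AUC summary and pairwise DeLong decisions."""

    auc_per_repeat: dict  # model -> list of AUC
    auc_mean: dict
    auc_sd: dict
    pairwise_p: dict  # (model_a, model_b) -> list of per-repeat p
    decisions: dict = field(default_factory=dict)
    alpha: float = 0.05

    def to_table(self) -> str:
        lines = ["model                     AUC (mean ± SD)"]
        for name in self.auc_mean:
            lines.append(
                f"{name:<25} {self.auc_mean[name]:.3f} ± {self.auc_sd[name]:.3f}"
            )
        for pair, dec in self.decisions.items():
            star = "*" if dec["significant"] else " "
            lines.append(
                f"{pair[0]} vs {pair[1]}: median p = {dec['median_p']:.4g}{star}"
            )
        return "\n".join(lines)


def build_report(results_by_model: dict, alpha: float = 0.05) -> EvalReport:
    """Table-style report from ``run_repeats`` outputs of several models.

    All models must have been run with the same master seed so that repeat k
    used the same split in every model; the per-repeat DeLong comparisons
    are then paired on identical test cases. A degenerate comparison (zero
    variance of the difference) is reported as p = 1: no evidence of a
    difference.
    """
    names = list(results_by_model)
    auc_per_repeat = {}
    for name in names:
        auc_per_repeat[name] = [
            roc_auc(r.test_scores, r.test_labels)[0] for r in results_by_model[name]
        ]
    pairwise = {}
    for a, b in combinations(names, 2):
        ps = []
        for ra, rb in zip(results_by_model[a], results_by_model[b]):
            if ra.test_ids != rb.test_ids:
                raise ValidationError(
                    f"repeat {ra.repeat}: models {a!r} and {b!r} were evaluated "
                    "on different test cases; rerun with a shared master seed"
                )
            try:
                _, p = delong_test(ra.test_scores, rb.test_scores, ra.test_labels)
            except DegenerateComparisonError:
                p = 1.0
            ps.append(p)
        pairwise[(a, b)] = ps
    report = EvalReport(
        auc_per_repeat=auc_per_repeat,
        auc_mean={k: float(np.mean(v)) for k, v in auc_per_repeat.items()},
        auc_sd={k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                for k, v in auc_per_repeat.items()},
        pairwise_p=pairwise,
        alpha=alpha,
    )
    if pairwise:
        report.decisions = aggregate_comparisons(pairwise, alpha=alpha)
    return report
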