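"""Histogram-class group comparison and ROC analysis.

For a chosen lifetime parameter, each subject's ROI values are reduced to a
normalized histogram at a fixed class width.  Per histogram class, the
subjects' class frequencies of the two groups are compared with a two-sided
Wilcoxon rank-sum test; the multiplicity threshold is th = s / nC with nC
the number of observed classes (plain Bonferroni bound; the Holm step-down
variant is available).  A significant class can act as a classifier, for
which ROC curve, AUC and a Youden-optimal cut-off are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import fsum

import numpy as np
from scipy import stats as sps

from .core import StudySet

__all__ = [
    "ClassComparison",
    "RocResult",
    "significance_threshold",
    "ranksum_test",
    "compare_groups",
    "roc_analysis",
]


def significance_threshold(s: float, n_classes: int) -> float:
    """Bonferroni-corrected per-class threshold th = s / nC."""
    if not 0 < s < 1:
        raise ValueError("significance level must lie in (0, 1)")
    if n_classes < 1:
        raise ValueError("need at least one histogram class")
    return s / n_classes


@lru_cache(maxsize=256)
def _ranksum_null(n1: int, ranks: tuple[float, ...]) -> np.ndarray:
    """Sorted null distribution of the rank-sum of the first sample.

    Enumerates every assignment of n1 of the pooled (mid)ranks to sample A;
    feasible for total n <= 20 (C(20, 10) = 184,756 subsets) and cached, so
    the common no-tie case costs the enumeration only once per sample size.
    """
    sums = [fsum(c) for c in combinations(ranks, n1)]
    return np.sort(np.asarray(sums))


def ranksum_test(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value (equal-medians null).

    Exact by full enumeration of rank assignments for small samples (total
    n <= 20; ties handled through midranks); tie-corrected normal
    approximation otherwise.  Symmetric in its arguments.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n = a.size, a.size + b.size
    if n <= 20:
        ranks = sps.rankdata(np.concatenate([a, b]))
        w_obs = float(ranks[:n1].sum())
        null = _ranksum_null(n1, tuple(np.sort(ranks)))
        mu = null.mean()
        dev = abs(w_obs - mu)
        p = float(np.mean(np.abs(null - mu) >= dev - 1e-9))
        return p
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(min(res.pvalue, 1.0))


@dataclass
class ClassComparison:
    edges: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    threshold: float
    best_class: int
    frequencies_a: np.ndarray
    frequencies_b: np.ndarray
    group_a: str
    group_b: str
    mode: str

    @property
    def n_classes(self) -> int:
        return self.p_values.size

    def best_class_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.frequencies_a[:, self.best_class],
            self.frequencies_b[:, self.best_class],
        )


def _subject_frequencies(
    study: StudySet, parameter: str, class_width: float
) -> tuple[np.ndarray, list[str], np.ndarray]:
    all_vals = []
    for s in study.subjects:
        v = s.results[parameter][s.roi_mask]
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError(f"subject {s.subject_id} has an empty ROI")
        all_vals.append(v)
    lo = min(v.min() for v in all_vals)
    hi = max(v.max() for v in all_vals)
    k0 = int(np.floor(lo / class_width))
    k1 = int(np.floor(hi / class_width)) + 1
    edges = np.arange(k0, k1 + 1) * class_width
    freqs = np.empty((len(all_vals), k1 - k0))
    for i, v in enumerate(all_vals):
        idx = np.floor(v / class_width).astype(int) - k0
        freqs[i] = np.bincount(idx, minlength=k1 - k0) / v.size
    return edges, [s.group for s in study.subjects], freqs


def compare_groups(
    study: StudySet,
    parameter: str,
    class_width: float,
    s: float = 0.05,
    mode: str = "bonferroni",
) -> ClassComparison:
    """Class-wise rank-sum comparison of two groups of subjects.

    The unit of analysis is one normalized class frequency per subject
    (testing volunteers against volunteers, not pooled pixels).  Classes
    with no observation in any subject are not tested; nC counts only
    observed classes.  Mode 'bonferroni' flags p < s / nC, mode 'holm'
    applies the step-down rule.
    """
    if mode not in ("bonferroni", "holm"):
        raise ValueError(f"unknown mode {mode!r}")
    group_a, group_b = study.validate_two_groups()
    edges, groups, freqs = _subject_frequencies(study, parameter, class_width)
    ga = np.array([g == group_a for g in groups])
    fa, fb = freqs[ga], freqs[~ga]
    observed = freqs.sum(axis=0) > 0
    n_classes = int(observed.sum())
    th = significance_threshold(s, n_classes)
    p = np.ones(freqs.shape[1])
    for c in np.nonzero(observed)[0]:
        p[c] = ranksum_test(fa[:, c], fb[:, c])
    if mode == "bonferroni":
        significant = observed & (p < th)
    else:
        significant = _holm_flags(p, observed, s)
    tested_p = np.where(observed, p, np.inf)
    best = int(np.argmin(tested_p))
    return ClassComparison(
        edges=edges,
        p_values=p,
        significant=significant,
        threshold=th,
        best_class=best,
        frequencies_a=fa,
        frequencies_b=fb,
        group_a=group_a,
        group_b=group_b,
        mode=mode,
    )


def _holm_flags(p: np.ndarray, observed: np.ndarray, s: float) -> np.ndarray:
    """Holm step-down rejections over the observed classes."""
    idx = np.nonzero(observed)[0]
    order = idx[np.argsort(p[idx])]
    n = idx.size
    flags = np.zeros(p.size, dtype=bool)
    for rank, c in enumerate(order):
        if p[c] < s / (n - rank):
            flags[c] = True
        else:
            break
    return flags


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str


def roc_analysis(values_patients, values_controls) -> RocResult:
    """ROC curve, AUC and Youden-optimal cut-off for a scalar classifier.

    Candidate thresholds are the midpoints of adjacent sorted unique pooled
    values (plus sentinels); both classification directions are tried and
    the one with the larger AUC kept.  The cut-off maximizes Youden's
    J = sensitivity + specificity - 1.
    """
    pat = np.asarray(values_patients, dtype=float)
    ctl = np.asarray(values_controls, dtype=float)
    if pat.size == 0 or ctl.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.unique(np.concatenate([pat, ctl]))
    mids = 0.5 * (pooled[:-1] + pooled[1:]) if pooled.size > 1 else np.array([])
    thresholds = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])

    best: RocResult | None = None
    for direction in (">", "<"):
        if direction == ">":
            tpr = np.array([(pat > t).mean() for t in thresholds])
            fpr = np.array([(ctl > t).mean() for t in thresholds])
        else:
            tpr = np.array([(pat < t).mean() for t in thresholds])
            fpr = np.array([(ctl < t).mean() for t in thresholds])
        order = np.lexsort((tpr, fpr))
        fpr_s, tpr_s = fpr[order], tpr[order]
        auc = float(np.trapezoid(tpr_s, fpr_s))
        j = tpr + (1.0 - fpr) - 1.0
        k = int(np.argmax(j))
        cand = RocResult(
            thresholds=thresholds,
            tpr=tpr_s,
            fpr=fpr_s,
            auc=auc,
            cutoff=float(thresholds[k]),
            sensitivity=float(tpr[k]),
            specificity=float(1.0 - fpr[k]),
            direction=direction,
        )
        if best is None or cand.auc > best.auc:
            best = cand
    return best
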