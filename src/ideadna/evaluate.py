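"""Scoring predicted binding energies against affinity data.

Strong/weak labels come from HT-SELEX-style M-word enrichment scores
(strong: score > 0.9; weak: score < 0.3, with fallback cutoffs 0.4 and 0.5
when fewer than three weak sequences remain). Because lower predicted energy
means stronger binding, classification metrics score the *negated* energy so
that conventional ROC/PR machinery applies with "strong binder" as the
positive class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm


def label_mword(scores, hi: float = 0.9, lo: float = 0.3,
                fallback_los=(0.4, 0.5), min_weak: int = 3) -> np.ndarray:
    """Label sequences by M-word score: 1 strong, 0 weak, -1 dropped.

    Scores above ``hi`` are strong; below ``lo`` weak. If fewer than
    ``min_weak`` weak sequences result, ``lo`` is raised through
    ``fallback_los`` in order; exhausting the fallbacks raises.
    """
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("M-word scores must lie in [0, 1]")
    for cutoff in (lo, *fallback_los):
        weak = s < cutoff
        if weak.sum() >= min_weak:
            labels = np.full(len(s), -1, dtype=int)
            labels[s > hi] = 1
            labels[weak] = 0
            return labels
    raise ValueError(
        f"fewer than {min_weak} weak sequences even at cutoff {max(fallback_los)}")


def _check_classes(labels):
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both strong and weak classes")
    return labels


def roc_auc(energies, labels) -> float:
    """ROC AUC of negated energies for the strong class (midrank ties)."""
    labels = _check_classes(labels)
    return float(skm.roc_auc_score(labels, -np.asarray(energies, dtype=float)))


def pr_auc(energies, labels) -> float:
    """Trapezoidal area under the precision-recall curve of −energy."""
    labels = _check_classes(labels)
    precision, recall, _ = skm.precision_recall_curve(
        labels, -np.asarray(energies, dtype=float))
    return float(skm.auc(recall, precision))


def balanced_pr_auc(energies, labels, n_subsamples: int = 20, seed: int = 0) -> float:
    """PR AUC after subsampling the majority class to the minority size.

    The class imbalance of SELEX tables inflates/deflates PR baselines, so
    the majority class is subsampled to match the minority class and the PR
    AUC averaged over ``n_subsamples`` seeded draws.
    """
    energies = np.asarray(energies, dtype=float)
    labels = _check_classes(np.asarray(labels))
    pos, neg = np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    if len(minority) == len(majority):
        return pr_auc(energies, labels)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_subsamples):
        sub = rng.choice(majority, size=len(minority), replace=False)
        idx = np.concatenate([minority, sub])
        vals.append(pr_auc(energies[idx], labels[idx]))
    return float(np.mean(vals))


def correlations(predicted, measured) -> tuple[float, float]:
    """(Pearson r, Spearman ρ) between predicted energies and measured ΔΔG."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    return float(sps.pearsonr(x, y).statistic), float(sps.spearmanr(x, y).statistic)


def density_separation(energies, labels, grid_points: int = 256) -> dict:
    """Kernel density summaries per class plus the class-median gap.

    Returns a dict with per-class KDE grids, medians, and
    ``median_gap`` = median(weak) − median(strong), positive when strong
    binders sit at lower predicted energy.
    """
    energies = np.asarray(energies, dtype=float)
    labels = _check_classes(np.asarray(labels))
    strong = energies[labels == 1]
    weak = energies[labels == 0]
    if len(strong) == 0 or len(weak) == 0:
        raise ValueError("both classes must be nonempty")
    lo = min(strong.min(), weak.min())
    hi = max(strong.max(), weak.max())
    pad = 0.1 * (hi - lo) or 1.0
    grid = np.linspace(lo - pad, hi + pad, grid_points)

    def kde(vals):
        if len(vals) < 2 or np.std(vals) == 0:
            return None
        return sps.gaussian_kde(vals)(grid)

    return {
        "grid": grid,
        "strong_density": kde(strong),
        "weak_density": kde(weak),
        "strong_median": float(np.median(strong)),
        "weak_median": float(np.median(weak)),
        "median_gap": float(np.median(weak) - np.median(strong)),
    }


def read_score_table(path, seq_col: str = "sequence", score_col: str = "score",
                     sep: str | None = None) -> pd.DataFrame:
    """Read a headered TSV/CSV of sequences and scores/affinities."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = {seq_col, score_col} - set(df.columns)
    if missing:
        raise ValueError(f"table lacks column(s) {sorted(missing)}")
    return df


def write_metrics_json(metrics: dict, path) -> None:
    import json
    with open(path, "w") as fh:
        json.dump({k: (v if not isinstance(v, np.ndarray) else v.tolist())
                   for k, v in metrics.items()}, fh, indent=2)
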