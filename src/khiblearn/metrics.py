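"""Evaluation suite: confusion metrics, ROC/AUC, correlated-AUC comparison,
position-specific residue enrichment (two-sample logo) and cluster quality.

AUC is computed as the normalised Mann-Whitney statistic with half credit for
ties, identical to trapezoidal integration of the step ROC.  Its standard
error follows Hanley & McNeil (1982), and two AUCs measured on the same
samples are compared with the correlated z-test of the same authors, with the
correlation term estimated as the mean of the within-positives and
within-negatives Pearson correlations of the two score vectors (a continuous
surrogate for the original table lookup).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import davies_bouldin_score, roc_curve, silhouette_score

from .windows import PAD, PeptideWindow

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Confusion counts, derived metrics, and (optionally) ROC/AUC."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sn: float
    sp: float
    pr: float
    f1: float
    mcc: float
    auc: float | None = None
    auc_se: float | None = None
    roc: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)

    def to_dict(self) -> dict:
        d = {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "ACC": self.acc, "SN": self.sn, "SP": self.sp, "PR": self.pr,
            "F1": self.f1, "MCC": self.mcc,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        return d

    def summary(self) -> str:
        parts = [f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                 for k, v in self.to_dict().items()]
        return "  ".join(parts)

    def plot_roc(self, ax=None):
        """Plot the ROC curve (requires a computed curve)."""
        if self.roc is None:
            raise ValueError("no ROC curve stored")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr = self.roc
        ax.plot(fpr, tpr, label=f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        return ax


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if y.size == 0:
        raise ValueError("empty input")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    return y


def confusion_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Binarise scores at the threshold and evaluate all confusion metrics.

    MCC is defined as 0 when its denominator vanishes; precision and F1 are 0
    when undefined.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    pr = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pr * sn / (pr + sn) if pr + sn else 0.0
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn) - (fp * fn)) / denom if denom else 0.0
    return MetricsReport(tp, tn, fp, fn, acc, sn, sp, pr, f1, float(mcc))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def auc_mann_whitney(labels, scores) -> float:
    """AUC as the normalised rank-sum statistic; ties count one half."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley & McNeil (1982) standard error of an AUC."""
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(labels, scores) -> MetricsReport:
    """AUC (with SE) and the step ROC curve, attached to a MetricsReport."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    auc = auc_mann_whitney(y, s)
    fpr, tpr, _ = roc_curve(y, s)
    report = confusion_metrics(y, s)
    report.auc = auc
    report.auc_se = hanley_mcneil_se(auc, int(y.sum()), int(len(y) - y.sum()))
    report.roc = (fpr, tpr)
    return report


def _paired_r(scores_a, scores_b, y) -> float:
    """Mean of within-positives and within-negatives Pearson correlations."""
    rs = []
    for cls in (1, 0):
        a, b = scores_a[y == cls], scores_b[y == cls]
        if len(a) > 1 and np.std(a) > 0 and np.std(b) > 0:
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(rs)) if rs else 0.0


def hanley_mcneil_compare(labels, scores_a, scores_b):
    """Correlated-AUC z-test on one sample set.

    Returns (auc_a, auc_b, z, p) with a two-sided normal p-value.  Identical
    score vectors give z = 0, p = 1.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("score vectors must cover the same samples")
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    auc_a = auc_mann_whitney(y, a)
    auc_b = auc_mann_whitney(y, b)
    se_a = hanley_mcneil_se(auc_a, n_pos, n_neg)
    se_b = hanley_mcneil_se(auc_b, n_pos, n_neg)
    r = _paired_r(a, b, y)
    var = se_a**2 + se_b**2 - 2 * r * se_a * se_b
    diff = auc_a - auc_b
    if var <= 0 or diff == 0:
        z = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    else:
        z = float(diff / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, z, p


# ---------------------------------------------------------------------------
# two-sample logo
# ---------------------------------------------------------------------------

@dataclass
class LogoReport:
    """Per (position offset, residue) frequency differences and significance.

    ``table`` columns: offset, residue, freq_pos, freq_neg, diff (percentage
    points, positive minus negative), p, flag in {enriched, depleted, ns}.
    The central position (offset 0) is excluded.
    """

    table: pd.DataFrame
    alpha: float
    flank: int

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table.flag != "ns"].reset_index(drop=True)

    def diff_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="residue", columns="offset", values="diff")

    def plot_heatmap(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 5))
        m = self.diff_matrix()
        vmax = np.abs(m.to_numpy()).max() or 1.0
        im = ax.imshow(m, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_yticks(range(len(m.index)), m.index)
        ax.set_xticks(range(len(m.columns)), m.columns, fontsize=7)
        ax.set_xlabel("offset from central K")
        plt.colorbar(im, ax=ax, label="frequency difference (pp)")
        return ax


def _as_seq(w) -> str:
    return w.sequence if isinstance(w, PeptideWindow) else str(w)


def two_sample_logo(
    pos_windows,
    neg_windows,
    alpha: float = 0.05,
    test: str = "welch",
) -> LogoReport:
    """Compare per-position residue frequencies between two window sets.

    For every non-central position and standard residue, the 0/1 occurrence
    indicators of the two groups are compared with a Welch two-sample t-test
    (``test="welch"``) or a two-proportion z-test (``test="ztest"``); the two
    agree asymptotically.  Windows with padding at a position are excluded
    there.  Cells with p <= alpha are flagged enriched (positive difference)
    or depleted (negative).
    """
    pos = [_as_seq(w) for w in pos_windows]
    neg = [_as_seq(w) for w in neg_windows]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 windows per group")
    lengths = {len(s) for s in pos} | {len(s) for s in neg}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    L = lengths.pop()
    if L % 2 == 0:
        raise ValueError("windows must have odd length")
    flank = L // 2

    pos_mat = np.frombuffer("".join(pos).encode(), dtype="S1").reshape(len(pos), L)
    neg_mat = np.frombuffer("".join(neg).encode(), dtype="S1").reshape(len(neg), L)
    pad = np.bytes_(PAD)

    rows = []
    for col in range(L):
        offset = col - flank
        if offset == 0:
            continue
        pcol = pos_mat[:, col]
        ncol = neg_mat[:, col]
        pcol = pcol[pcol != pad]
        ncol = ncol[ncol != pad]
        if len(pcol) < 2 or len(ncol) < 2:
            continue
        for res in AA20:
            rb = np.bytes_(res)
            xi = (pcol == rb).astype(float)
            yi = (ncol == rb).astype(float)
            fp_, fn_ = xi.mean(), yi.mean()
            diff = 100.0 * (fp_ - fn_)
            if test == "welch":
                if xi.std() == 0 and yi.std() == 0:
                    p = 1.0
                else:
                    p = float(stats.ttest_ind(xi, yi, equal_var=False).pvalue)
            elif test == "ztest":
                n1, n2 = len(xi), len(yi)
                pool = (xi.sum() + yi.sum()) / (n1 + n2)
                se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
                p = float(2 * stats.norm.sf(abs(fp_ - fn_) / se)) if se > 0 else 1.0
            else:
                raise ValueError(f"unknown test {test!r}")
            if p <= alpha and diff > 0:
                flag = "enriched"
            elif p <= alpha and diff < 0:
                flag = "depleted"
            else:
                flag = "ns"
            rows.append((offset, res, fp_, fn_, diff, p, flag))
    table = pd.DataFrame(
        rows, columns=["offset", "residue", "freq_pos", "freq_neg", "diff", "p", "flag"]
    )
    return LogoReport(table, alpha, flank)


# ---------------------------------------------------------------------------
# cluster quality
# ---------------------------------------------------------------------------

def cluster_quality(values, labels) -> tuple[float, float]:
    """Silhouette score and Davies-Bouldin index of a labelled point set.

    Accepts a per-sample real vector (e.g. predicted probabilities) or
    low-dimensional coordinates (e.g. a 2-D projection).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    y = _check_binary(labels)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all points identical")
    sil = float(silhouette_score(x, y, metric="euclidean"))
    dbi = float(davies_bouldin_score(x, y))
    return sil, dbi
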