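"""Multi-class Fisher (linear) discriminant models for wound age estimation.

The wound-age model classifies an animal's expression vector into one of
the 13 design groups (control, 4h, ..., 48h) with a pooled-covariance
linear discriminant: class k scores

    s_k(x) = x' S^-1 m_k - 1/2 m_k' S^-1 m_k + log pi_k

with class means m_k, pooled within-class covariance S = W / (n - k), and
equal priors by default (the design is balanced at 6 animals per group).
Model strength is summarised by Wilks' lambda = det(W) / det(T) — the
within-class share of the total scatter, near 0 for well-separated
classes — with significance from Bartlett's chi-square approximation.
Out-of-sample accuracy is estimated by leave-one-out cross-validation,
accumulating a confusion matrix over the held-out predictions.

All variables of a gene subset enter together; there is no stepwise
selection, and no merging or hierarchical grouping of time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .are_screen import GO_CATEGORIES, GeneRecord, SUBGROUPS
from .qpcr import ExpressionMatrix


@dataclass
class DiscriminantModel:
    """A fitted multi-class linear discriminant with its diagnostics."""

    gene_subset: list[str]
    class_labels: list[str]
    class_means: np.ndarray  # (k, p)
    pooled_cov: np.ndarray  # (p, p)
    priors: np.ndarray  # (k,)
    wilks_lambda: float
    p_value: float
    loocv_accuracy: Optional[float] = None
    confusion: Optional[pd.DataFrame] = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class labels for rows of ``x`` by highest discriminant score."""
        codes = _predict_codes(
            np.atleast_2d(np.asarray(x, dtype=float)),
            self.class_means, self.pooled_cov, self.priors,
        )
        return np.asarray(self.class_labels, dtype=object)[codes]


def _check_design(n: int, k: int, p: int) -> None:
    if k < 2:
        raise ValueError("need >= 2 classes")
    if n - k <= p:
        raise ValueError(
            f"within-class degrees of freedom (n - k = {n - k}) must exceed "
            f"the number of genes (p = {p})"
        )


def _class_stats(
    x: np.ndarray, codes: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class means, within-class scatter W, and class counts."""
    p = x.shape[1]
    means = np.empty((k, p))
    counts = np.empty(k, dtype=int)
    w = np.zeros((p, p))
    for c in range(k):
        block = x[codes == c]
        counts[c] = len(block)
        means[c] = block.mean(axis=0)
        centred = block - means[c]
        w += centred.T @ centred
    return means, w, counts


def _pooled_cov(w: np.ndarray, n: int, k: int, ridge: float) -> np.ndarray:
    s = w / (n - k)
    if ridge > 0:
        s = s + ridge * np.eye(s.shape[0])
    return s


def _predict_codes(
    x: np.ndarray, means: np.ndarray, cov: np.ndarray, priors: np.ndarray
) -> np.ndarray:
    try:
        cov_inv_means = np.linalg.solve(cov, means.T)  # (p, k)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-class covariance is singular; consider the "
            "ridge_epsilon option"
        ) from exc
    linear = x @ cov_inv_means  # (n, k)
    const = -0.5 * np.einsum("kp,pk->k", means, cov_inv_means) + np.log(priors)
    return np.argmax(linear + const, axis=1)


def _prepare(
    expr: ExpressionMatrix, gene_subset: Optional[Sequence[str]]
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    genes = list(gene_subset) if gene_subset is not None else list(expr.values.columns)
    x = expr.values[genes].to_numpy(dtype=float)
    labels = expr.groups.to_numpy()
    classes = list(pd.unique(labels))
    code_of = {c: i for i, c in enumerate(classes)}
    codes = np.array([code_of[l] for l in labels])
    return x, codes, classes, genes


def wilks_lambda(
    expr: ExpressionMatrix, gene_subset: Optional[Sequence[str]] = None
) -> tuple[float, float]:
    """Wilks' lambda det(W)/det(T) with Bartlett's chi-square p-value.

    The test statistic is ``-(n - 1 - (p + k) / 2) ln(lambda)`` on
    ``p (k - 1)`` degrees of freedom.
    """
    x, codes, classes, genes = _prepare(expr, gene_subset)
    n, p = x.shape
    k = len(classes)
    _check_design(n, k, p)
    _, w, _ = _class_stats(x, codes, k)
    centred = x - x.mean(axis=0)
    t = centred.T @ centred
    sign_t, logdet_t = np.linalg.slogdet(t)
    sign_w, logdet_w = np.linalg.slogdet(w)
    if sign_t <= 0:
        raise ValueError(
            "total scatter matrix is singular (collinear genes); consider "
            "the ridge_epsilon option or a smaller gene subset"
        )
    if sign_w <= 0:
        raise ValueError(
            "within-class scatter matrix is singular; consider the "
            "ridge_epsilon option or a smaller gene subset"
        )
    lam = float(np.exp(logdet_w - logdet_t))
    chi2 = -(n - 1 - (p + k) / 2.0) * (logdet_w - logdet_t)
    df = p * (k - 1)
    return lam, float(stats.chi2.sf(chi2, df))


def fit_lda(
    expr: ExpressionMatrix,
    gene_subset: Optional[Sequence[str]] = None,
    priors: str = "equal",
    ridge_epsilon: float = 0.0,
) -> DiscriminantModel:
    """Fit the pooled-covariance linear discriminant on a gene subset.

    ``priors`` is 'equal' (default, balanced design) or 'proportional'.
    ``ridge_epsilon`` adds a diagonal stabiliser to the pooled covariance
    (off by default).
    """
    x, codes, classes, genes = _prepare(expr, gene_subset)
    n, p = x.shape
    k = len(classes)
    _check_design(n, k, p)
    means, w, counts = _class_stats(x, codes, k)
    cov = _pooled_cov(w, n, k, ridge_epsilon)
    pri = (
        np.full(k, 1.0 / k) if priors == "equal" else counts / counts.sum()
    )
    lam, pval = wilks_lambda(expr, genes)
    return DiscriminantModel(
        gene_subset=genes,
        class_labels=[str(c) for c in classes],
        class_means=means,
        pooled_cov=cov,
        priors=pri,
        wilks_lambda=lam,
        p_value=pval,
    )


def loocv_accuracy(
    expr: ExpressionMatrix,
    gene_subset: Optional[Sequence[str]] = None,
    priors: str = "equal",
    ridge_epsilon: float = 0.0,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated accuracy and confusion matrix.

    Each animal is classified by a model refitted on the remaining n - 1;
    the confusion matrix accumulates held-out predictions (rows: true
    group, columns: predicted).
    """
    x, codes, classes, genes = _prepare(expr, gene_subset)
    n, p = x.shape
    k = len(classes)
    _check_design(n - 1, k, p)
    counts = np.bincount(codes, minlength=k)
    if (counts < 2).any():
        bad = [classes[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(
            f"class(es) {bad} would lose all training samples in a fold"
        )
    confusion = np.zeros((k, k), dtype=int)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        means, w, cts = _class_stats(x[mask], codes[mask], k)
        cov = _pooled_cov(w, n - 1, k, ridge_epsilon)
        pri = np.full(k, 1.0 / k) if priors == "equal" else cts / cts.sum()
        pred = _predict_codes(x[i : i + 1], means, cov, pri)[0]
        confusion[codes[i], pred] += 1
    accuracy = float(np.trace(confusion) / n)
    confusion_df = pd.DataFrame(confusion, index=classes, columns=classes)
    return accuracy, confusion_df


def standard_gene_subsets(records: Iterable[GeneRecord]) -> dict[str, list[str]]:
    """The 11 screening groupings: ARE+/-, CC/BP/MF, and the six crosses."""
    targets = [r for r in records if not r.is_reference and r.subgroup not in (None, "excluded")]
    subsets: dict[str, list[str]] = {}
    for status in ("ARE+", "ARE-"):
        subsets[status] = [r.symbol for r in targets if r.are_status == status]
    for go in GO_CATEGORIES:
        subsets[go] = [r.symbol for r in targets if r.go_category == (go,)]
    for sub in SUBGROUPS:
        subsets[sub] = [r.symbol for r in targets if r.subgroup == sub]
    return {name: genes for name, genes in subsets.items() if genes}


def discriminant_summary(
    expr: ExpressionMatrix,
    records: Iterable[GeneRecord],
    priors: str = "equal",
    ridge_epsilon: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Wilks' lambda, p-value, and LOOCV accuracy for every gene grouping.

    Returns the summary table (one row per grouping) and the per-grouping
    confusion matrices.
    """
    rows = []
    confusions: dict[str, pd.DataFrame] = {}
    for name, genes in standard_gene_subsets(records).items():
        model = fit_lda(expr, genes, priors=priors, ridge_epsilon=ridge_epsilon)
        acc, conf = loocv_accuracy(
            expr, genes, priors=priors, ridge_epsilon=ridge_epsilon
        )
        confusions[name] = conf
        rows.append(
            {
                "subset": name,
                "n_genes": len(genes),
                "wilks_lambda": model.wilks_lambda,
                "p_value": model.p_value,
                "loocv_accuracy_pct": acc * 100.0,
            }
        )
    return pd.DataFrame(rows).set_index("subset"), confusions
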