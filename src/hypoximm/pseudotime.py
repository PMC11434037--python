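"""Pseudotime ordering, trend testing, and the transcription-factor screen.

Cells are ordered along a one-dimensional differentiation axis (first
principal component of log-normalized expression, oriented so the root
population sits at the origin and rescaled to [0, 1]); externally supplied
pseudotime is accepted everywhere.  Per-gene trends along pseudotime are
tested by an F-test of a natural cubic spline fit (df = 3) against the
intercept-only model, with Benjamini-Hochberg q-values across genes.

The TF screen then applies three filters per dataset — significance
(p < 0.05 and q < 0.05), direction (end-of-trajectory mean above the
start mean), and cross-dataset consistency (passing in at least half of
all datasets) — and classifies each retained TF's Spearman correlation
with the hypoxia score as positive, negative, or non-significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class TrendResult:
    gene: str
    p_value: float
    q_value: float
    direction: str  # increasing / decreasing / flat
    start_mean: float
    end_mean: float


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def order_pseudotime(
    expr: ExpressionMatrix, root_label: str, labels: Sequence[str]
) -> np.ndarray:
    """First-PC ordering of cells, rooted at ``root_label`` and rescaled to
    [0, 1].

    The axis is oriented so the root-labeled cells' mean projection is
    minimal; a degenerate (constant) first component raises.
    """
    labels = np.asarray(labels, dtype=object)
    if root_label not in set(labels):
        raise ValueError(f"root label {root_label!r} absent")
    if expr.n_samples < 10:
        raise ValueError("pseudotime ordering needs >= 10 cells")
    X = expr.lognorm().values.T  # cells x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("expression is constant; first PC is degenerate")
    proj = U[:, 0] * s[0]
    if proj[labels == root_label].mean() > proj.mean():
        proj = -proj
    lo, hi = proj.min(), proj.max()
    return (proj - lo) / (hi - lo)


def _natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis (R ns() convention): boundary knots at the
    data range, df-1 interior knots at quantiles, linear beyond the range."""
    x = np.asarray(x, dtype=float)
    probs = np.linspace(0, 1, df + 1)[1:-1]
    interior = np.quantile(x, probs)
    lo, hi = x.min(), x.max()
    knots = np.concatenate([[lo], interior, [hi]])

    def d(k: np.ndarray | float) -> np.ndarray:
        num = np.clip(x - k, 0, None) ** 3 - np.clip(x - hi, 0, None) ** 3
        return num / (hi - k)

    cols = [x]
    for k in knots[:-2]:
        cols.append(d(k) - d(knots[-2]))
    return np.column_stack(cols[:df])


def trend_test(
    expr_gene: np.ndarray, pseudotime: np.ndarray, gene: str = "gene"
) -> TrendResult:
    """Spline-vs-constant F-test of one gene's trend along pseudotime.

    Direction is the sign of (top-tercile mean - bottom-tercile mean) of
    pseudotime-stratified expression, ``flat`` when the difference is
    negligible; a constant gene yields p = 1 and flat.  The q-value is
    filled in by :func:`trend_test_genes`.
    """
    y = np.asarray(expr_gene, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("trend test needs >= 10 cells")
    lo_t, hi_t = np.quantile(t, [1 / 3, 2 / 3])
    start_mean = float(y[t <= lo_t].mean())
    end_mean = float(y[t >= hi_t].mean())
    if np.allclose(y, y[0]):
        return TrendResult(gene, 1.0, np.nan, "flat", start_mean, end_mean)

    X = _natural_spline_basis(t, df=3)
    X = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    q = X.shape[1] - 1
    dof = n - X.shape[1]
    if rss1 <= 0 or dof <= 0:
        p = 0.0 if rss0 > rss1 else 1.0
    else:
        f = ((rss0 - rss1) / q) / (rss1 / dof)
        p = float(scipy.stats.f.sf(f, q, dof))
    diff = end_mean - start_mean
    direction = "flat" if abs(diff) < 1e-8 else ("increasing" if diff > 0 else "decreasing")
    return TrendResult(gene, p, np.nan, direction, start_mean, end_mean)


def trend_test_genes(
    expr: ExpressionMatrix,
    pseudotime: np.ndarray,
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Trend-test each gene and attach BH q-values across the tested set."""
    genes = list(genes) if genes is not None else list(expr.gene_ids)
    present = set(expr.gene_ids)
    genes = [g for g in genes if g in present]
    idx = expr.gene_index(genes)
    results = [
        trend_test(expr.values[i], pseudotime, gene=expr.gene_ids[i]) for i in idx
    ]
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "start_mean": [r.start_mean for r in results],
            "end_mean": [r.end_mean for r in results],
        }
    ).set_index("gene")
    df["q_value"] = bh_qvalues(df["p_value"].to_numpy())
    return df[["p_value", "q_value", "direction", "start_mean", "end_mean"]]


def filter_differentiation_tfs(
    per_dataset_results: Sequence[pd.DataFrame],
    tf_list: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Three-stage TF filter across datasets.

    A TF passes within a dataset when p < alpha AND q < alpha AND its
    end-of-trajectory mean exceeds its start mean; it is retained when it
    passes in at least half of all datasets (ties at exactly half retained).
    Returns per-TF pass counts and the retention flag.
    """
    if not list(tf_list):
        logger.warning("empty TF list; nothing to filter")
        return pd.DataFrame(columns=["n_pass", "n_datasets", "retained"])
    n = len(per_dataset_results)
    counts = {}
    for tf in tf_list:
        n_pass = 0
        for res in per_dataset_results:
            if tf not in res.index:
                continue
            row = res.loc[tf]
            if (
                row["p_value"] < alpha
                and row["q_value"] < alpha
                and row["end_mean"] > row["start_mean"]
            ):
                n_pass += 1
        counts[tf] = n_pass
    df = pd.DataFrame(
        {
            "n_pass": pd.Series(counts),
            "n_datasets": n,
        }
    )
    df.index.name = "tf"
    df["retained"] = df["n_pass"] >= n / 2
    return df


def classify_tf_hypoxia(
    tf_expr: np.ndarray, hypoxia_scores: np.ndarray, alpha: float = 0.05
) -> tuple[str, float, float]:
    """Classify one TF's Spearman relation to the hypoxia score in a dataset:
    ``positive`` / ``negative`` when significant, else ``ns``."""
    x = np.asarray(tf_expr, dtype=float)
    y = np.asarray(hypoxia_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("TF expression and hypoxia scores must be matched")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return "ns", np.nan, np.nan
    rs, p = scipy.stats.spearmanr(x, y)
    if p < alpha and rs > 0:
        return "positive", float(rs), float(p)
    if p < alpha and rs < 0:
        return "negative", float(rs), float(p)
    return "ns", float(rs), float(p)


def classify_tfs_across_datasets(
    datasets: Sequence[tuple[ExpressionMatrix, np.ndarray]],
    tfs: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-TF proportion of datasets in each hypoxia-correlation class.

    ``datasets`` pairs each expression matrix with its per-cell hypoxia
    score vector.
    """
    rows = []
    for tf in tfs:
        tally = {"positive": 0, "negative": 0, "ns": 0}
        n_seen = 0
        for expr, hyp in datasets:
            if tf not in set(expr.gene_ids):
                continue
            n_seen += 1
            x = expr.values[expr.gene_ids.index(tf)]
            cls, _, _ = classify_tf_hypoxia(x, hyp, alpha)
            tally[cls] += 1
        denom = max(n_seen, 1)
        rows.append(
            (tf, n_seen, *(tally[c] / denom for c in ("positive", "negative", "ns")))
        )
    return pd.DataFrame(
        rows, columns=["tf", "n_datasets", "prop_positive", "prop_negative", "prop_ns"]
    ).set_index("tf")


def subset_fold_change(
    subset_labels: Sequence[str],
    hypoxia_group_labels: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Fold change of cell-subset proportions between hypoxia-high and -low
    groups, with ``pseudocount`` cells added to every subset count."""
    subs = np.asarray(subset_labels, dtype=object)
    grps = np.asarray(hypoxia_group_labels, dtype=object)
    if subs.shape != grps.shape:
        raise ValueError("label vectors must be matched")
    for g in ("high", "low"):
        if not (grps == g).any():
            raise ValueError(f"hypoxia group {g!r} is empty")
    subsets = sorted(set(subs))
    rows = []
    for g in ("high", "low"):
        counts = np.array([(subs[grps == g] == s).sum() for s in subsets], dtype=float)
        counts += pseudocount
        rows.append(counts / counts.sum())
    prop_high, prop_low = rows
    fc = prop_high / prop_low
    return pd.DataFrame(
        {
            "prop_high": prop_high,
            "prop_low": prop_low,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
        },
        index=pd.Index(subsets, name="subset"),
    )
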