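"""Single-sample gene-signature scoring.

Two scorers are provided.  The rank-based scorer is a weighted
Kolmogorov-Smirnov random walk over within-sample expression ranks
(ssGSEA-style, exponent 0.25 by default): genes are visited in decreasing
expression order; signature hits advance the hit CDF by their
rank^exponent weight (normalized to sum 1), misses advance the miss CDF
uniformly, and the score is the mean running difference.  Being a pure
function of within-sample ranks, it is invariant to any strictly monotone
transformation of expression.  The mean-scaled scorer — used at the
single-cell level — averages per-gene z-scores (across samples, ddof=1)
over the signature.

The 15-gene HIF1A-associated hypoxia signature ships with the package and
is exposed as :func:`hypoxia_signature`.
"""

from __future__ import annotations

import importlib.resources
import logging
from typing import Sequence

import numpy as np
import scipy.stats

from .types import ExpressionMatrix, ScoreVector, SignatureSet

logger = logging.getLogger(__name__)

HYPOXIA_GENES = (
    "ACOT7", "ADM", "ALDOA", "CDKN3", "ENO1", "LDHA", "MIF", "MRPS17",
    "NDRG1", "P4HA1", "PGAM1", "SLC2A1", "TPI1", "TUBB6", "VEGFA",
)

TEX_MARKERS = (
    "PDCD1", "LAG3", "HAVCR2", "CD8A", "CD8B", "CD3E", "ENTPD1",
    # the published marker list spells ITGAE as "TGAE"; both are carried so
    # that whichever symbol a matrix uses is matched
    "TGAE", "ITGAE",
    "BATF", "NR4A1",
)


def hypoxia_signature() -> SignatureSet:
    """The packaged 15-gene hypoxia signature as a SignatureSet."""
    from .io import read_gmt

    with importlib.resources.as_file(
        importlib.resources.files("hypoximm.data") / "hypoxia15.gmt"
    ) as p:
        return read_gmt(p)


def tex_signature() -> SignatureSet:
    """The packaged exhausted-T-cell marker set."""
    from .io import read_gmt

    with importlib.resources.as_file(
        importlib.resources.files("hypoximm.data") / "tex_markers.gmt"
    ) as p:
        return read_gmt(p)


def _resolve_signature(signature, name: str | None = None) -> tuple[str, list[str]]:
    if isinstance(signature, SignatureSet):
        if name is None:
            if len(signature) != 1:
                raise ValueError("signature set has several sets; pass a name")
            name = next(iter(signature))
        return name, signature[name]
    return name or "signature", list(signature)


def score_rank_enrichment(
    expr: ExpressionMatrix,
    signature,
    weight_exponent: float = 0.25,
    name: str | None = None,
) -> ScoreVector:
    """Weighted-KS single-sample enrichment score per column.

    Requires at least 2 signature genes present in the matrix, and the
    signature must be a proper subset of the matrix genes (a signature that
    covers every gene leaves no misses to walk against).
    """
    sig_name, genes = _resolve_signature(signature, name)
    present = set(expr.gene_ids)
    matched = [g for g in genes if g in present]
    if len(matched) < 2:
        raise ValueError(
            f"signature {sig_name!r}: only {len(matched)} genes matched; need >= 2"
        )
    if len(matched) >= expr.n_genes:
        raise ValueError(
            f"signature {sig_name!r} covers all {expr.n_genes} genes; "
            "no background remains"
        )
    hit = np.zeros(expr.n_genes, dtype=bool)
    hit[expr.gene_index(matched)] = True

    n_genes, n_samples = expr.n_genes, expr.n_samples
    n_miss = n_genes - hit.sum()
    scores = np.empty(n_samples)
    for j in range(n_samples):
        v = expr.values[:, j]
        # average ranks: the most-expressed gene has rank n_genes
        ranks = scipy.stats.rankdata(v, method="average")
        # walk order: decreasing expression; ties broken by gene order
        order = np.lexsort((np.arange(n_genes), -v))
        hit_o = hit[order]
        w = np.where(hit_o, ranks[order] ** weight_exponent, 0.0)
        w_sum = w.sum()
        p_hit = np.cumsum(w) / w_sum
        p_miss = np.cumsum(~hit_o) / n_miss
        scores[j] = float(np.sum(p_hit - p_miss) / n_genes)
    return ScoreVector(list(expr.sample_ids), scores, sig_name, "rank_enrichment")


def score_mean_scaled(
    expr: ExpressionMatrix, signature, name: str | None = None
) -> ScoreVector:
    """Mean of per-gene z-scores (across samples, ddof=1) over the signature.

    Zero-variance genes contribute 0.  Intended for single-cell columns.
    """
    sig_name, genes = _resolve_signature(signature, name)
    idx = expr.gene_index(genes)
    if idx.size == 0:
        raise ValueError(f"signature {sig_name!r}: no genes matched the matrix")
    sub = expr.values[idx]
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True) if expr.n_samples > 1 else np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (sub - mean) / sd, 0.0)
    return ScoreVector(
        list(expr.sample_ids), z.mean(axis=0), sig_name, "mean_scaled"
    )


def median_split(scores: ScoreVector) -> np.ndarray:
    """Split samples at the median score: above -> ``high``, at or below ->
    ``low``.  All-identical scores admit no split and raise."""
    if len(scores.sample_ids) < 2:
        raise ValueError("median split needs at least 2 samples")
    med = float(np.median(scores.score))
    if np.all(scores.score == scores.score[0]):
        raise ValueError("all scores identical; no median split possible")
    return np.where(scores.score > med, "high", "low").astype(object)


def score_signatures(
    expr: ExpressionMatrix,
    signatures: SignatureSet,
    method: str = "rank_enrichment",
    weight_exponent: float = 0.25,
) -> dict[str, ScoreVector]:
    """Score every set in a SignatureSet with the chosen method."""
    out = {}
    for sig_name in signatures:
        if method == "rank_enrichment":
            out[sig_name] = score_rank_enrichment(
                expr, signatures, weight_exponent, name=sig_name
            )
        elif method == "mean_scaled":
            out[sig_name] = score_mean_scaled(expr, signatures, name=sig_name)
        else:
            raise ValueError(f"unknown scoring method {method!r}")
    return out
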