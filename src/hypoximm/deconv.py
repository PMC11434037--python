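"""Spot deconvolution and co-localization of ALCAM-high macrophages with
exhausted T cells.

Spot composition is estimated by non-negative least squares against a
reference of per-cell-type mean expression restricted to type-specific
marker genes; proportions are the normalized NNLS weights.  Macrophage
spots are split at the cohort median of normalized ALCAM expression;
exhausted-T-cell (Tex) spots are gated on a marker-set enrichment score.
A Tex spot counts as co-localized with ALCAM-high macrophages when it is
itself ALCAM-high or any immediate hexagonal neighbor (the first outer
circle) is, and the exhaustion-score contrast between co-localized and
non-co-localized Tex spots is a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .regions import NeighborGraph, RegionAssignment
from .scoring import score_rank_enrichment
from .types import ExpressionMatrix, ScoreVector, SpatialSlide

logger = logging.getLogger(__name__)


@dataclass
class ReferenceSignatureMatrix:
    """Per-cell-type mean expression over marker genes (linear scale)."""

    gene_ids: list[str]
    cell_type_ids: list[str]
    values: np.ndarray  # genes x cell types
    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_type_ids)):
            raise ValueError("reference shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("reference means must be non-negative")
        if len(self.cell_type_ids) < 2:
            raise ValueError("need at least 2 cell types")


def build_reference(
    sc_expr: ExpressionMatrix,
    cell_labels: Sequence[str],
    top_k: int = 50,
    min_cells: int = 10,
) -> ReferenceSignatureMatrix:
    """Per-type mean of linear-normalized expression over marker genes.

    Markers are the ``top_k`` most type-specific genes per type by
    log-fold-change of the type mean against the mean of all other cells.
    """
    labels = np.asarray(cell_labels, dtype=object)
    if labels.shape != (sc_expr.n_samples,):
        raise ValueError("one label per cell required")
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("need at least 2 distinct cell types")
    for t in types:
        n = int((labels == t).sum())
        if n < min_cells:
            raise ValueError(f"cell type {t!r} has only {n} cells (< {min_cells})")

    lin = sc_expr.linear_norm().values if sc_expr.value_kind == "raw_counts" \
        else np.expm1(sc_expr.values)
    means = np.column_stack([lin[:, labels == t].mean(axis=1) for t in types])
    markers: dict[str, list[str]] = {}
    for j, t in enumerate(types):
        rest = means[:, [k for k in range(len(types)) if k != j]].mean(axis=1)
        lfc = np.log1p(means[:, j]) - np.log1p(rest)
        order = np.argsort(-lfc, kind="mergesort")[:top_k]
        markers[t] = [sc_expr.gene_ids[i] for i in order]
    union = sorted({g for gs in markers.values() for g in gs})
    gidx = sc_expr.gene_index(union)
    return ReferenceSignatureMatrix(
        gene_ids=[sc_expr.gene_ids[i] for i in gidx],
        cell_type_ids=types,
        values=means[gidx],
        markers=markers,
    )


def deconvolve_spots(
    slide: SpatialSlide, ref: ReferenceSignatureMatrix
) -> pd.DataFrame:
    """NNLS spot deconvolution over the reference's marker-gene union.

    Returns a spot x cell-type proportion frame (rows sum to 1; all-NaN rows
    mark spots whose NNLS weights are all zero).
    """
    shared = [g for g in ref.gene_ids if g in set(slide.expr.gene_ids)]
    if not shared:
        raise ValueError("no genes shared between the slide and the reference")
    for t in ref.cell_type_ids:
        n_shared = len(set(ref.markers[t]) & set(shared))
        if n_shared < 2:
            raise ValueError(
                f"cell type {t!r}: only {n_shared} marker genes shared with slide"
            )
    ref_idx = {g: i for i, g in enumerate(ref.gene_ids)}
    S = ref.values[[ref_idx[g] for g in shared]]
    expr = slide.expr.linear_norm() if slide.expr.value_kind == "raw_counts" \
        else slide.expr
    Y = expr.subset_genes(shared).values

    n_spots = slide.n_spots
    props = np.full((n_spots, len(ref.cell_type_ids)), np.nan)
    for s in range(n_spots):
        w, _ = scipy.optimize.nnls(S, Y[:, s])
        total = w.sum()
        if total > 0:
            props[s] = w / total
    n_missing = int(np.isnan(props[:, 0]).sum())
    if n_missing:
        logger.info("deconvolution: %d spots with all-zero weights", n_missing)
    return pd.DataFrame(props, index=slide.spot_ids, columns=ref.cell_type_ids)


def gate_alcam_macrophages(
    slide: SpatialSlide,
    props: pd.DataFrame,
    mac_threshold: float = 0.1,
    gene: str = "ALCAM",
    mac_type: str = "macrophage",
) -> pd.Series:
    """Median split of macrophage spots by log-normalized ALCAM expression.

    Spots with macrophage proportion >= ``mac_threshold`` are macrophage
    spots; among them, normalized expression of ``gene`` above the median
    labels ``alcam_high_mac``, at or below labels ``alcam_low_mac``; other
    spots are ``none``.
    """
    if gene not in set(slide.expr.gene_ids):
        raise ValueError(f"gene {gene!r} absent from the slide")
    if mac_type not in props.columns:
        raise ValueError(f"cell type {mac_type!r} absent from proportions")
    mac_mask = props[mac_type].reindex(slide.spot_ids).to_numpy() >= mac_threshold
    out = pd.Series("none", index=slide.spot_ids, dtype=object)
    if not mac_mask.any():
        logger.warning("no spot reaches macrophage proportion %.2f", mac_threshold)
        return out
    logn = slide.expr.lognorm()
    g_row = logn.values[logn.gene_ids.index(gene)]
    vals = g_row[mac_mask]
    med = float(np.median(vals))
    labels = np.where(vals > med, "alcam_high_mac", "alcam_low_mac")
    out.iloc[np.flatnonzero(mac_mask)] = labels
    return out


def identify_tex_spots(
    slide: SpatialSlide,
    tex_signature,
    quantile: float = 0.75,
    props: Optional[pd.DataFrame] = None,
    tcell_type: str = "t_cell",
    min_tcell_prop: float = 0.05,
) -> list[str]:
    """Gate exhausted-T-cell spots on the Tex marker-set enrichment score.

    Tex spots score at or above the ``quantile`` threshold; when spot
    proportions are supplied, they must also carry a T-cell proportion of
    at least ``min_tcell_prop``.  Spots with zero expression of every
    marker are never Tex.
    """
    scores = score_rank_enrichment(slide.expr, tex_signature)
    matched = [g for g in _signature_genes(tex_signature) if g in set(slide.expr.gene_ids)]
    if len(matched) < 3:
        raise ValueError(f"only {len(matched)} Tex markers matched; need >= 3")
    expressed = slide.expr.subset_genes(matched).values.sum(axis=0) > 0
    thr = float(np.quantile(scores.score, quantile))
    mask = (scores.score >= thr) & expressed
    if props is not None and tcell_type in props.columns:
        tprop = props[tcell_type].reindex(slide.spot_ids).to_numpy()
        mask &= np.nan_to_num(tprop) >= min_tcell_prop
    return [s for s, m in zip(slide.spot_ids, mask) if m]


def _signature_genes(signature) -> list[str]:
    from .types import SignatureSet

    if isinstance(signature, SignatureSet):
        name = next(iter(signature))
        return signature[name]
    return list(signature)


def colocalize(
    texs: Sequence[str],
    alcam_high_spots: Sequence[str],
    graph: NeighborGraph,
) -> pd.DataFrame:
    """First-outer-circle co-localization of Tex spots with ALCAM-high spots.

    A Tex spot is co-localized when it is itself ALCAM-high, or when any
    immediate lattice neighbor is.  Returns one row per Tex spot with the
    flag and the ALCAM-high partner spots responsible.
    """
    lookup = {s: i for i, s in enumerate(graph.spot_ids)}
    missing = [s for s in list(texs) + list(alcam_high_spots) if s not in lookup]
    if missing:
        raise ValueError(f"spots absent from the graph: {missing[:10]}")
    alcam_set = set(alcam_high_spots)
    rows = []
    for t in texs:
        partners = []
        if t in alcam_set:
            partners.append(t)
        for v in graph.adjacency[lookup[t]]:
            if graph.spot_ids[v] in alcam_set:
                partners.append(graph.spot_ids[v])
        rows.append(
            (t, "colocalized" if partners else "not_colocalized",
             ";".join(sorted(set(partners))))
        )
    return pd.DataFrame(rows, columns=["spot_id", "flag", "partners"]).set_index(
        "spot_id"
    )


def compare_colocalized_exhaustion(
    exhaustion_scores: ScoreVector, coloc: pd.DataFrame
) -> dict:
    """Two-sided Wilcoxon rank-sum contrast of exhaustion scores between
    co-localized and non-co-localized Tex spots."""
    sc = exhaustion_scores.to_series()
    grp_a = sc[coloc.index[coloc["flag"] == "colocalized"]].to_numpy()
    grp_b = sc[coloc.index[coloc["flag"] == "not_colocalized"]].to_numpy()
    if len(grp_a) < 2 or len(grp_b) < 2:
        raise ValueError(
            f"need >= 2 spots per group; got {len(grp_a)} colocalized, "
            f"{len(grp_b)} not"
        )
    res = scipy.stats.mannwhitneyu(grp_a, grp_b, alternative="two-sided")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_colocalized": float(np.median(grp_a)),
        "median_not_colocalized": float(np.median(grp_b)),
        "n_colocalized": int(len(grp_a)),
        "n_not_colocalized": int(len(grp_b)),
    }


def region_enrichment(
    labels: pd.Series, regions: RegionAssignment, positive_label: str | None = None
) -> pd.DataFrame:
    """Observed/expected enrichment of labeled spots per region with Fisher
    exact p-values on the labeled x in-region 2x2 table.

    ``labels`` is either boolean per spot or categorical with
    ``positive_label`` naming the class of interest.
    """
    lab = labels.reindex(regions.spot_ids)
    flag = (lab == positive_label) if positive_label is not None else lab.astype(bool)
    flag = flag.to_numpy()
    region = np.asarray(regions.label, dtype=object)
    total, n_flag = len(flag), int(flag.sum())
    rows = []
    for r in ("Mal", "Bdy", "nMal"):
        in_r = region == r
        a = int((flag & in_r).sum())
        n_r = int(in_r.sum())
        if n_flag == 0 or n_r == 0:
            ratio, p = 0.0, 1.0
        else:
            expected = n_flag * n_r / total
            ratio = a / expected if expected > 0 else np.nan
            table = [[a, n_flag - a], [n_r - a, total - n_flag - n_r + a]]
            p = float(scipy.stats.fisher_exact(table)[1])
        rows.append((r, n_r, a, ratio, p))
    return pd.DataFrame(
        rows, columns=["region", "n_spots", "n_labeled", "obs_over_exp", "fisher_p"]
    ).set_index("region")
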