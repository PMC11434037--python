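"""Immunophenoscore (IPS) from weighted, category-averaged sample Z-scores.

Four categories contribute: effector cells (activated and effector-memory
CD4/CD8 T cells, +1), suppressor cells (Tregs, MDSCs, -1), MHC molecules
(+1), and checkpoints/immunomodulators (ICOS and CD27 +1; inhibitory
checkpoints -1).  Each determinant is a single gene or a metagene; its
value is the mean of the member genes' sample Z-scores times the weight.
The category value averages its determinants, and the IPS is the sum of
the four category values.  The score is invariant under per-gene affine
rescaling of expression, and the default configuration ships with the
package (gene families not fully enumerated by the construction are
flagged ``unlisted_default`` and overridable).
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

CATEGORIES = ("effector_cells", "suppressor_cells", "mhc", "checkpoints")


@dataclass
class Determinant:
    name: str
    genes: list[str]
    weight: int

    def __post_init__(self) -> None:
        if self.weight not in (1, -1):
            raise ValueError(f"determinant {self.name!r}: weight must be +1 or -1")
        if not self.genes:
            raise ValueError(f"determinant {self.name!r}: empty gene list")


@dataclass
class IPSConfig:
    categories: dict[str, list[Determinant]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.categories)
        if missing:
            raise ValueError(f"missing IPS categories: {sorted(missing)}")

    @classmethod
    def from_dict(cls, data: dict) -> "IPSConfig":
        cats = {
            cat: [
                Determinant(d["name"], list(d["genes"]), int(d["weight"]))
                for d in dets
            ]
            for cat, dets in data["categories"].items()
        }
        return cls(categories=cats)

    @classmethod
    def from_json(cls, path) -> "IPSConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def default(cls) -> "IPSConfig":
        with importlib.resources.as_file(
            importlib.resources.files("hypoximm.data") / "ips_default.json"
        ) as p:
            return cls.from_json(p)


def sample_zscores(expr: ExpressionMatrix, genes) -> pd.DataFrame:
    """Per-gene Z-score across samples (ddof=1; zero-variance genes -> 0).

    Genes absent from the matrix are recorded as missing (dropped rows,
    logged); at least two samples are required.
    """
    if expr.n_samples < 2:
        raise ValueError("sample Z-scores need >= 2 samples")
    present = set(expr.gene_ids)
    matched = [g for g in genes if g in present]
    missing = [g for g in genes if g not in present]
    if missing:
        logger.warning("genes absent from matrix, excluded: %s", missing[:10])
    sub = expr.subset_genes(matched)
    mean = sub.values.mean(axis=1, keepdims=True)
    sd = sub.values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (sub.values - mean) / sd, 0.0)
    return pd.DataFrame(z, index=sub.gene_ids, columns=sub.sample_ids)


def determinant_value(Z: pd.DataFrame, det: Determinant) -> np.ndarray | None:
    """Mean Z over the determinant's genes times its weight; None (with a
    warning) when every member gene is missing from the Z table."""
    rows = [g for g in det.genes if g in Z.index]
    if not rows:
        logger.warning("determinant %s dropped: no genes matched", det.name)
        return None
    return det.weight * Z.loc[rows].to_numpy().mean(axis=0)


def compute_ips(expr: ExpressionMatrix, config: IPSConfig | None = None) -> pd.DataFrame:
    """Per-sample IPS with the four category components.

    Each category value is the mean of its determinants' weighted values,
    and the IPS is the sum over categories.  A category whose determinants
    all fail to match raises.
    """
    if config is None:
        config = IPSConfig.default()
    all_genes = sorted(
        {g for dets in config.categories.values() for d in dets for g in d.genes}
    )
    Z = sample_zscores(expr, all_genes)
    out = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    total = np.zeros(expr.n_samples)
    for cat in CATEGORIES:
        values = []
        for det in config.categories[cat]:
            v = determinant_value(Z, det)
            if v is not None:
                values.append(v)
        if not values:
            raise ValueError(f"IPS category {cat!r}: no determinant matched the matrix")
        cat_value = np.mean(values, axis=0)
        out[cat] = cat_value
        total = total + cat_value
    out["ips"] = total
    return out
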