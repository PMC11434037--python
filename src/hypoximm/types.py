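"""Core in-memory containers shared across the pipeline.

Everything downstream operates on three containers: an expression matrix
(genes x samples, where "samples" may be bulk samples, spatial spots, or
single cells), a spatial slide (expression plus hexagonal-lattice spot
coordinates), and named gene signatures.  They are deliberately thin
wrappers over numpy/pandas with validated invariants, so that every module
can rely on unique identifiers and consistent shapes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SpatialSlide",
    "SignatureSet",
    "ScoreVector",
    "RegionAssignment",
    "SurvivalCohort",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an input file or table violates its format contract."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({x for x in ids if x in seen or seen.add(x)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} identifiers: {dups[:10]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with identifier lists.

    ``value_kind`` flags whether ``values`` holds raw counts (non-negative
    integers) or log-normalized expression (counts-per-10k, log1p).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str = "raw_counts"

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.value_kind not in ("raw_counts", "lognorm"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.value_kind == "raw_counts" and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise ValueError("raw_counts values must be integers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of the listed genes (genes absent are skipped)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids),
            self.values[idx], self.value_kind,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return ExpressionMatrix(
            list(self.gene_ids), [self.sample_ids[j] for j in idx],
            self.values[:, idx], self.value_kind,
        )

    def linear_norm(self, scale: float = 1e4) -> "ExpressionMatrix":
        """Counts-per-``scale`` column normalization on the linear scale."""
        totals = self.values.sum(axis=0)
        totals = np.where(totals == 0, 1.0, totals)
        vals = self.values / totals * scale
        out = dataclasses.replace(self, values=vals, value_kind="lognorm")
        return out

    def lognorm(self, scale: float = 1e4) -> "ExpressionMatrix":
        """Counts-per-``scale`` then log1p; no-op if already log-normalized."""
        if self.value_kind == "lognorm":
            return self
        lin = self.linear_norm(scale)
        return dataclasses.replace(lin, values=np.log1p(lin.values))


@dataclass
class SpatialSlide:
    """Expression matrix whose columns are capture spots on a hex lattice."""

    expr: ExpressionMatrix
    array_row: np.ndarray
    array_col: np.ndarray
    px_x: np.ndarray
    px_y: np.ndarray
    truth_region: Optional[np.ndarray] = None
    truth_props: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        n = self.expr.n_samples
        for name in ("array_row", "array_col", "px_x", "px_y"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        coords = np.column_stack([self.px_x, self.px_y])
        _, counts = np.unique(coords, axis=0, return_counts=True)
        if np.any(counts > 1):
            raise ValueError("two spots share identical pixel coordinates")
        if self.truth_region is not None:
            self.truth_region = np.asarray(self.truth_region, dtype=object)
            if self.truth_region.shape != (n,):
                raise ValueError("truth_region length mismatch")
        if self.truth_props is not None and len(self.truth_props) != n:
            raise ValueError("truth_props row count mismatch")

    @property
    def spot_ids(self) -> list[str]:
        return self.expr.sample_ids

    @property
    def n_spots(self) -> int:
        return self.expr.n_samples

    def subset_spots(self, spots: Sequence[str]) -> "SpatialSlide":
        lookup = {s: j for j, s in enumerate(self.spot_ids)}
        idx = np.array([lookup[s] for s in spots], dtype=int)
        return SpatialSlide(
            expr=self.expr.subset_samples(spots),
            array_row=self.array_row[idx],
            array_col=self.array_col[idx],
            px_x=self.px_x[idx],
            px_y=self.px_y[idx],
            truth_region=None if self.truth_region is None else self.truth_region[idx],
            truth_props=None if self.truth_props is None else self.truth_props.iloc[idx],
        )


@dataclass
class SignatureSet:
    """Named gene sets with optional per-gene +1/-1 direction weights."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    weights: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"signature {name!r} has an empty gene list")
            if len(set(genes)) != len(genes):
                raise ValueError(f"signature {name!r} contains duplicate genes")
            if name in self.weights and len(self.weights[name]) != len(genes):
                raise ValueError(f"signature {name!r} weight length mismatch")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class ScoreVector:
    """Per-sample score for one signature, tagged with the scoring method."""

    sample_ids: list[str]
    score: np.ndarray
    signature_name: str
    method: str

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.sample_ids),):
            raise ValueError("one score per sample required")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("scores must be finite")
        if self.method not in ("rank_enrichment", "mean_scaled"):
            raise ValueError(f"unknown method {self.method!r}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.sample_ids, name=self.signature_name)


@dataclass
class RegionAssignment:
    """Per-spot region label (Mal / Bdy / nMal) with extrapolation layer."""

    spot_ids: list[str]
    label: np.ndarray
    layer: np.ndarray

    def __post_init__(self) -> None:
        self.spot_ids = _check_unique(self.spot_ids, "spot")
        self.label = np.asarray(self.label, dtype=object)
        self.layer = np.asarray(self.layer, dtype=int)
        n = len(self.spot_ids)
        if self.label.shape != (n,) or self.layer.shape != (n,):
            raise ValueError("label/layer length mismatch")
        bad = set(self.label) - {"Mal", "Bdy", "nMal"}
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.label, "layer": self.layer}, index=self.spot_ids
        )

    def spots_with(self, label: str) -> list[str]:
        return [s for s, lab in zip(self.spot_ids, self.label) if lab == label]


@dataclass
class SurvivalCohort:
    """Per-sample score with survival outcome and optional ICB annotations."""

    sample_ids: list[str]
    score: np.ndarray
    time: np.ndarray
    event: np.ndarray
    response: Optional[np.ndarray] = None
    timepoint: Optional[np.ndarray] = None
    patient_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        self.score = np.asarray(self.score, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        for name in ("score", "time", "event"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} length mismatch")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event flags must be 0/1")
        for name in ("response", "timepoint", "patient_id"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=object)
                if arr.shape != (n,):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"score": self.score, "time": self.time, "event": self.event},
            index=self.sample_ids,
        )
        for name in ("response", "timepoint", "patient_id"):
            arr = getattr(self, name)
            if arr is not None:
                df[name] = arr
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalCohort":
        return cls(
            sample_ids=[str(i) for i in df.index],
            score=df["score"].to_numpy(float),
            time=df["time"].to_numpy(float),
            event=df["event"].to_numpy(int),
            response=df["response"].to_numpy(object) if "response" in df else None,
            timepoint=df["timepoint"].to_numpy(object) if "timepoint" in df else None,
            patient_id=df["patient_id"].to_numpy(object) if "patient_id" in df else None,
        )
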