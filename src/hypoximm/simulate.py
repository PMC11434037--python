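"""Synthetic data generators with known ground truth.

Three families of generators emulate the data structures the analyses
assume:

* :func:`simulate_slide` — a hexagonal spatial-transcriptomics slide with a
  malignant core, a one-ring tumor boundary, and a non-malignant exterior.
  Each spot is a Dirichlet mixture of cell types (malignant, macrophage,
  T cell, stromal); counts are negative-binomial around the mixture of
  cell-type expression programs, and the hypoxia program rises from the
  slide exterior toward the core along an exponential gradient.
* :func:`simulate_bulk_cohort` — a staged bulk cohort in which a latent
  hypoxia activity grows linearly with morphological stage and drives an
  exponential survival hazard and the probability of checkpoint-blockade
  response; a subset of patients carries paired pre-/on-treatment profiles.
* :func:`simulate_tcells` — single-cell T-cell datasets ordered along a
  naive-to-exhausted pseudotime axis, with naive markers falling and
  exhaustion markers plus the hypoxia program rising, and with designated
  transcription factors rising in a configurable number of datasets (to
  exercise the cross-dataset consistency filter).

All generators are pure functions of their parameter objects: the same
parameters (including seed) give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import HYPOXIA_GENES
from .types import ExpressionMatrix, SignatureSet, SpatialSlide

CELL_TYPES = ("malignant", "macrophage", "t_cell", "stromal")

_MALIGNANCY_CORE = ("EPCAM", "KRT8", "KRT18", "KRT19", "CDH1", "MKI67")
_MACROPHAGE_CORE = ("CD68", "CD163", "LYZ", "ALCAM", "MRC1", "ITGAM")
_TEX_PROGRAM = (
    "PDCD1", "LAG3", "HAVCR2", "CD8A", "CD8B", "CD3E", "ENTPD1", "ITGAE",
    "BATF", "NR4A1",
)
_EFFECTOR_CORE = ("GZMB", "PRF1", "IFNG", "GZMK", "KLRG1")
_STROMA_CORE = ("COL1A1", "COL1A2", "COL3A1", "DCN", "LUM", "FBLN1")
_NAIVE_MARKERS = ("TCF7", "SELL", "CCR7", "LEF1", "IL7R")
_EXHAUSTION_MARKERS = ("PDCD1", "LAG3", "HAVCR2", "TIGIT", "CTLA4", "ENTPD1", "TOX")


def default_programs() -> SignatureSet:
    """Default cell-type expression programs for slide simulation."""
    return SignatureSet(
        sets={
            "hypoxia": list(HYPOXIA_GENES),
            "malignancy": list(_MALIGNANCY_CORE)
            + [f"MALIG{i:02d}" for i in range(7, 31)],
            "macrophage": list(_MACROPHAGE_CORE)
            + [f"MACRO{i:02d}" for i in range(7, 21)],
            "tex": list(_TEX_PROGRAM),
            "effector": list(_EFFECTOR_CORE)
            + [f"EFFEC{i:02d}" for i in range(6, 16)],
            # stroma carries its own strong program (collagens etc.) so
            # that every region has comparable numbers of highly expressed
            # competitor genes and rank-based scores track the hypoxia
            # gradient rather than regional program content
            "stroma": list(_STROMA_CORE)
            + [f"STROM{i:02d}" for i in range(7, 21)],
        }
    )


def _default_alphas() -> dict[str, tuple[float, ...]]:
    # concentration over (malignant, macrophage, t_cell, stromal):
    # the core is dominated by malignant cells, the boundary ring is a
    # macrophage/T-cell-rich mixed zone, the exterior is stromal
    return {
        "Mal": (16.0, 1.0, 0.5, 0.5),
        "Bdy": (4.0, 4.0, 3.0, 1.0),
        "nMal": (0.3, 1.5, 1.5, 6.0),
    }


@dataclass
class SlideSimParams:
    """Parameters of the hex-lattice slide generator.

    ``hypoxia_gradient`` is the log-fold increase of the hypoxia program
    from slide exterior to core; ``program_strength`` is the log-fold
    elevation of each cell type's program over baseline;
    ``alcam_boundary_lfc`` adds an ALCAM log-fold bump to boundary spots,
    reproducing the boundary enrichment of ALCAM-high macrophages.
    """

    n_rings: int = 8
    core_radius: int = 3
    n_genes: int = 400
    program_genes: Optional[SignatureSet] = None
    hypoxia_gradient: float = 1.5
    mix_dirichlet_alpha: Optional[dict[str, tuple[float, ...]]] = None
    libsize_mean: float = 8000.0
    nb_dispersion: float = 10.0
    program_strength: float = 2.5
    alcam_boundary_lfc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.core_radius < self.n_rings:
            raise ValueError("require 0 <= core_radius < n_rings")
        if self.hypoxia_gradient < 0:
            raise ValueError("hypoxia_gradient must be >= 0")
        if self.libsize_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("libsize_mean and nb_dispersion must be > 0")
        if self.program_genes is None:
            self.program_genes = default_programs()
        if self.mix_dirichlet_alpha is None:
            self.mix_dirichlet_alpha = _default_alphas()
        for region, alpha in self.mix_dirichlet_alpha.items():
            if len(alpha) != len(CELL_TYPES) or any(a <= 0 for a in alpha):
                raise ValueError(f"invalid Dirichlet alpha for region {region!r}")

    @classmethod
    def strong_separation(cls, **kwargs) -> "SlideSimParams":
        """Strong-program-separation preset: regional cell-type mixtures are
        nearly deterministic (Dirichlet concentrations scaled 4x, so the
        within-region mixture variance drops 4-fold) and programs are more
        strongly expressed.  This is the well-separated regime in which
        region recovery is expected to approach the truth labels."""
        alphas = {
            region: tuple(4.0 * a for a in alpha)
            for region, alpha in _default_alphas().items()
        }
        kwargs.setdefault("mix_dirichlet_alpha", alphas)
        kwargs.setdefault("program_strength", 3.0)
        return cls(**kwargs)


def hex_lattice(n_rings: int) -> pd.DataFrame:
    """Axial hexagonal lattice of radius ``n_rings``.

    Pixel centers use x = q + r/2, y = r * sqrt(3)/2, giving unit spacing
    between all 6 neighbors.  ``ring`` is the hex distance from the origin.
    """
    rows = []
    R = n_rings
    for q in range(-R, R + 1):
        for r in range(max(-R, -q - R), min(R, -q + R) + 1):
            ring = (abs(q) + abs(r) + abs(q + r)) // 2
            rows.append((q, r, ring, q + r / 2.0, r * np.sqrt(3) / 2.0))
    df = pd.DataFrame(rows, columns=["q", "r", "ring", "px_x", "px_y"])
    return df.sort_values(["ring", "q", "r"], kind="mergesort").reset_index(drop=True)


def _gene_panel(params: SlideSimParams) -> list[str]:
    genes: list[str] = []
    seen: set[str] = set()
    for _, members in params.program_genes.items():
        for g in members:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    i = 0
    while len(genes) < params.n_genes:
        g = f"BG{i:04d}"
        if g not in seen:
            genes.append(g)
            seen.add(g)
        i += 1
    return genes


def _type_profiles(params: SlideSimParams, genes: list[str]) -> np.ndarray:
    """Linear-scale mean expression per gene (rows) per cell type (cols)."""
    gidx = {g: i for i, g in enumerate(genes)}
    M = np.ones((len(genes), len(CELL_TYPES)))
    boost = np.exp(params.program_strength)
    program_to_type = {
        "malignancy": "malignant",
        "macrophage": "macrophage",
        "tex": "t_cell",
        "effector": "t_cell",
        "stroma": "stromal",
    }
    for program, ctype in program_to_type.items():
        if program not in params.program_genes:
            continue
        j = CELL_TYPES.index(ctype)
        factor = boost if program != "effector" else np.exp(params.program_strength / 2)
        for g in params.program_genes[program]:
            if g in gidx:
                M[gidx[g], j] *= factor
    return M


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + mean^2 / dispersion."""
    mean = np.clip(mean, 1e-12, None)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


def simulate_slide(params: SlideSimParams) -> SpatialSlide:
    """Generate a hex-lattice slide with core / boundary / exterior truth."""
    rng = np.random.default_rng(params.seed)
    lattice = hex_lattice(params.n_rings)
    n_spots = len(lattice)
    genes = _gene_panel(params)
    M = _type_profiles(params, genes)
    gidx = {g: i for i, g in enumerate(genes)}
    hyp_idx = np.array(
        [gidx[g] for g in params.program_genes["hypoxia"] if g in gidx], dtype=int
    )
    alcam_idx = gidx.get("ALCAM")

    ring = lattice["ring"].to_numpy()
    region = np.where(
        ring <= params.core_radius,
        "Mal",
        np.where(ring == params.core_radius + 1, "Bdy", "nMal"),
    ).astype(object)

    counts = np.zeros((len(genes), n_spots))
    props = np.zeros((n_spots, len(CELL_TYPES)))
    # global scale: gene means are the cell-type mixture itself (hypoxia
    # rows scaled by the ring gradient), calibrated so a typical spot's
    # total is libsize_mean; composition never rescales the hypoxia means
    denom = float(M.mean(axis=1).sum())
    for s in range(n_spots):
        alpha = np.asarray(params.mix_dirichlet_alpha[region[s]], dtype=float)
        w = rng.dirichlet(alpha)
        props[s] = w
        profile = M @ w
        hfac = np.exp(params.hypoxia_gradient * (1.0 - ring[s] / params.n_rings))
        profile[hyp_idx] *= hfac
        if alcam_idx is not None and region[s] == "Bdy":
            profile[alcam_idx] *= np.exp(params.alcam_boundary_lfc)
        mu = params.libsize_mean * profile / denom
        counts[:, s] = _nb_draw(rng, mu, params.nb_dispersion)

    spot_ids = [f"spot_{i:04d}" for i in range(n_spots)]
    expr = ExpressionMatrix(genes, spot_ids, counts, "raw_counts")
    return SpatialSlide(
        expr=expr,
        array_row=(lattice["r"] + params.n_rings).to_numpy(),
        array_col=(lattice["q"] + params.n_rings).to_numpy(),
        px_x=lattice["px_x"].to_numpy(),
        px_y=lattice["px_y"].to_numpy(),
        truth_region=region,
        truth_props=pd.DataFrame(props, index=spot_ids, columns=list(CELL_TYPES)),
    )


def simulate_celltype_reference(
    params: SlideSimParams, n_cells_per_type: int = 30, seed: int = 1
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Single cells drawn from each cell type's program, for reference building."""
    rng = np.random.default_rng(seed)
    genes = _gene_panel(params)
    M = _type_profiles(params, genes)
    cells, labels = [], []
    for j, ctype in enumerate(CELL_TYPES):
        profile = M[:, j] / M[:, j].sum()
        for _ in range(n_cells_per_type):
            cells.append(_nb_draw(rng, 2000.0 * profile, params.nb_dispersion))
            labels.append(ctype)
    ids = [f"cell_{i:04d}" for i in range(len(cells))]
    expr = ExpressionMatrix(genes, ids, np.column_stack(cells), "raw_counts")
    return expr, np.asarray(labels, dtype=object)


def shift_program(
    slide: SpatialSlide, genes: Sequence[str], spot_ids: Sequence[str], lfc: float
) -> SpatialSlide:
    """Return a slide with the listed genes' counts scaled by exp(lfc) at the
    listed spots (rounded to keep integer counts).  Used to plant localized
    expression effects with known ground truth."""
    gi = slide.expr.gene_index(genes)
    lookup = {s: j for j, s in enumerate(slide.spot_ids)}
    sj = np.array([lookup[s] for s in spot_ids], dtype=int)
    vals = slide.expr.values.copy()
    vals[np.ix_(gi, sj)] = np.round(vals[np.ix_(gi, sj)] * np.exp(lfc))
    expr = dataclasses.replace(slide.expr, values=vals)
    return dataclasses.replace(slide, expr=expr)


@dataclass
class CohortSimParams:
    """Parameters of the staged bulk-cohort generator.

    ``hypoxia_slope`` shifts the latent hypoxia activity per stage;
    ``survival_hazard_ratio`` is the log-hazard increase per unit of that
    latent activity; responders' on-treatment hypoxia program shifts down
    and non-responders' up by ``on_treatment_shift``.
    """

    n_per_stage: int = 20
    n_stages: int = 9
    hypoxia_slope: float = 0.5
    survival_hazard_ratio: float = 1.0
    censor_rate: float = 0.3
    n_genes: int = 300
    baseline_hazard: float = 1.0 / 1000.0
    noise_sd: float = 0.2
    paired_fraction: float = 0.4
    on_treatment_shift: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.n_genes < len(HYPOXIA_GENES) + 10:
            raise ValueError("n_genes too small for the gene panel")


def _bulk_counts(
    rng: np.random.Generator,
    base_log_mean: np.ndarray,
    hyp_idx: np.ndarray,
    activity: float,
    dispersion: float = 10.0,
) -> np.ndarray:
    log_mean = base_log_mean.copy()
    log_mean[hyp_idx] += activity
    return _nb_draw(rng, np.exp(log_mean), dispersion)


def simulate_bulk_cohort(
    params: CohortSimParams,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Staged bulk cohort with hypoxia-driven survival and ICB response.

    The metadata frame carries stage, survival time (days) and event flag,
    RECIST response class, pre/on timepoint, patient id, and the generating
    latent hypoxia activity under ``true_hypoxia`` (ground truth; for tests
    only, never a pipeline input).
    """
    rng = np.random.default_rng(params.seed)
    genes = list(HYPOXIA_GENES) + [
        f"BG{i:04d}" for i in range(params.n_genes - len(HYPOXIA_GENES))
    ]
    base_log_mean = rng.normal(np.log(5.0), 1.0, size=len(genes))
    hyp_idx = np.arange(len(HYPOXIA_GENES))

    n = params.n_per_stage * params.n_stages
    stages = np.repeat(np.arange(params.n_stages), params.n_per_stage)
    center = (params.n_stages - 1) / 2.0
    activity = params.hypoxia_slope * (stages - center) + rng.normal(
        0.0, params.noise_sd, size=n
    )

    hazard = params.baseline_hazard * np.exp(params.survival_hazard_ratio * activity)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < params.censor_rate
    time = np.where(censored, t_event * rng.uniform(0.1, 1.0, size=n), t_event)
    time = np.maximum(time, 1e-3)
    event = (~censored).astype(int)

    p_resp = 1.0 / (1.0 + np.exp(1.5 * activity))
    responder = rng.random(n) < p_resp
    resp_class = np.where(
        responder,
        np.where(rng.random(n) < 0.5, "CR", "PR"),
        np.where(rng.random(n) < 0.7, "PD", "SD"),
    ).astype(object)

    cols, ids, meta_rows = [], [], []
    paired = rng.random(n) < params.paired_fraction
    for i in range(n):
        sid = f"S{i:04d}_pre"
        ids.append(sid)
        cols.append(_bulk_counts(rng, base_log_mean, hyp_idx, activity[i]))
        meta_rows.append(
            (sid, f"P{i:04d}", stages[i], time[i], event[i], resp_class[i],
             "pre", activity[i])
        )
        if paired[i]:
            shift = -params.on_treatment_shift if responder[i] else params.on_treatment_shift
            a_on = activity[i] + shift
            sid_on = f"S{i:04d}_on"
            ids.append(sid_on)
            cols.append(_bulk_counts(rng, base_log_mean, hyp_idx, a_on))
            meta_rows.append(
                (sid_on, f"P{i:04d}", stages[i], time[i], event[i], resp_class[i],
                 "on", a_on)
            )

    expr = ExpressionMatrix(genes, ids, np.column_stack(cols), "raw_counts")
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "patient_id", "stage", "time", "event",
                 "response", "timepoint", "true_hypoxia"],
    ).set_index("sample_id")
    return expr, meta


def tcell_gene_panel(tf_names: Sequence[str], n_genes: int = 200) -> list[str]:
    genes: list[str] = []
    seen: set[str] = set()
    for g in (*_NAIVE_MARKERS, *_EXHAUSTION_MARKERS, *HYPOXIA_GENES, *tf_names):
        if g not in seen:
            seen.add(g)
            genes.append(g)
    i = 0
    while len(genes) < n_genes:
        g = f"BG{i:04d}"
        if g not in seen:
            genes.append(g)
            seen.add(g)
        i += 1
    return genes


def simulate_tcells(
    n_cells: int,
    n_datasets: int,
    exhaustion_tf_set: Sequence[str],
    seed: int = 0,
    tf_increase_counts: Optional[dict[str, int]] = None,
    n_genes: int = 200,
    trend_lfc: float = 1.5,
    noise_sd: float = 0.4,
) -> list[tuple[ExpressionMatrix, np.ndarray, np.ndarray]]:
    """Single-cell T-cell datasets along a naive-to-exhausted axis.

    ``tf_increase_counts`` maps a TF name to the number of datasets (the
    first k of ``n_datasets``) in which its expression rises along
    pseudotime; unlisted TFs rise in every dataset.  Returns one
    (expression, true pseudotime, subset labels) triple per dataset.
    """
    if n_cells < 50:
        raise ValueError("need >= 50 cells per dataset")
    rng = np.random.default_rng(seed)
    genes = tcell_gene_panel(exhaustion_tf_set, n_genes)
    gidx = {g: i for i, g in enumerate(genes)}
    tf_increase_counts = tf_increase_counts or {}

    slopes_base = np.zeros(len(genes))
    for g in _NAIVE_MARKERS:
        slopes_base[gidx[g]] = -trend_lfc
    for g in _EXHAUSTION_MARKERS:
        slopes_base[gidx[g]] = trend_lfc
    for g in HYPOXIA_GENES:
        slopes_base[gidx[g]] = trend_lfc * 2 / 3

    out = []
    for d in range(n_datasets):
        slopes = slopes_base.copy()
        for tf in exhaustion_tf_set:
            k = tf_increase_counts.get(tf, n_datasets)
            slopes[gidx[tf]] = trend_lfc if d < k else 0.0
        t = rng.uniform(0.0, 1.0, size=n_cells)
        base = rng.normal(1.0, 0.5, size=len(genes))
        log_expr = (
            base[:, None]
            + slopes[:, None] * t[None, :]
            + rng.normal(0.0, noise_sd, size=(len(genes), n_cells))
        )
        values = np.exp(log_expr)
        labels = np.where(t < 1 / 3, "NaiveLike",
                          np.where(t < 2 / 3, "Effector", "Tex")).astype(object)
        ids = [f"d{d}_cell{i:04d}" for i in range(n_cells)]
        expr = ExpressionMatrix(genes, ids, values, "lognorm")
        out.append((expr, t, labels))
    return out
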