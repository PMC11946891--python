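"""Synthetic data generators with known ground truth.

Three simulators mirror the statistical structure each analysis stage
assumes: negative-binomially dispersed guide counts with log-normal
library skew and planted per-condition selection effects (pooled screen);
cells carrying one true guide over an ambient guide background, with
cluster labels drawn from gene-specific shifted cluster probabilities
(CROP-seq); and homogeneous Poisson localization background with planted
dense discs (dSTORM fields).  Every simulator is bit-reproducible under a
fixed seed, and the returned truth object partitions the simulated units
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from shapely.geometry import Point, box

from .cropseq import CellGuideCapture
from .screen import NONTARGETING, GuideLibrary, ScreenCounts
from .smlm import LocalizationSet


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimTruth:
    """Ground truth of a simulation; exactly one record per simulated unit.

    Only the fields relevant to the producing simulator are populated.
    """

    planted_effects: dict | None = None  # gene -> {(organ, treatment): multiplier}
    planted_directions: dict | None = None  # gene -> "enriched" | "depleted"
    cell_guides: list | None = None  # per cell: list of true guide ids
    cell_doublet: list | None = None  # per cell: bool
    gene_cluster_probs: dict | None = None  # gene -> probability vector
    point_labels: np.ndarray | None = None  # per point: -1 background, k cluster index


# ---------------------------------------------------------------------------
# pooled screen


@dataclass(frozen=True)
class ScreenCondition:
    organ: str
    treatment: str
    batch: str
    n_replicates: int


#: Default multi-organ design: one IgG control arm plus checkpoint-blockade
#: arms across the tumour and the two metastatic niches, batched by organ.
DEFAULT_SCREEN_CONDITIONS = (
    ScreenCondition("tumour", "IgG", "tumour", 3),
    ScreenCondition("tumour", "anti-PD-1", "tumour", 3),
    ScreenCondition("lung", "anti-PD-1", "lung", 3),
    ScreenCondition("liver", "anti-PD-1", "liver", 3),
)


@dataclass
class ScreenSimConfig:
    """Design of a simulated pooled screen.

    ``planted_effects`` maps gene -> {(organ, treatment): abundance
    multiplier}; multipliers act on pre-normalization guide abundance
    (selection before sampling) and >1 means positive selection.
    Counts are negative binomial with variance mu + dispersion * mu^2.
    """

    n_genes: int = 200
    guides_per_gene: int = 5
    n_nontargeting: int = 25
    conditions: Sequence[ScreenCondition] = DEFAULT_SCREEN_CONDITIONS
    n_t0_replicates: int = 3
    reads_per_sample: int = 1_000_000
    library_skew_sdlog: float = 0.5
    dispersion: float = 0.2
    planted_effects: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=dict
    )
    seed: int = 0


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion*mu^2 (Poisson if 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gene_name(i: int) -> str:
    return f"gene{i + 1:04d}"


def simulate_screen(config: ScreenSimConfig) -> tuple[GuideLibrary, ScreenCounts, SimTruth]:
    """Simulate a pooled screen with planted per-condition selection."""
    if config.n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    if config.guides_per_gene < 1:
        raise ConfigurationError("guides_per_gene must be >= 1")
    if not config.conditions or any(c.n_replicates < 1 for c in config.conditions):
        raise ConfigurationError("every condition needs >= 1 replicate")
    if config.n_t0_replicates < 1:
        raise ConfigurationError("need >= 1 T0 replicate")
    genes = [gene_name(i) for i in range(config.n_genes)]
    gene_set = set(genes)
    for g, eff in config.planted_effects.items():
        if g not in gene_set:
            raise ConfigurationError(f"planted gene {g!r} not in library")
        for cond, mult in eff.items():
            if mult < 0:
                raise ConfigurationError(f"negative multiplier for {g!r} in {cond}")

    rows = []
    for i, g in enumerate(genes):
        for j in range(config.guides_per_gene):
            rows.append((f"{g}_g{j + 1}", g, False))
    for j in range(config.n_nontargeting):
        rows.append((f"nt_{j + 1:03d}", NONTARGETING, True))
    lib = GuideLibrary(pd.DataFrame(rows, columns=["guide_id", "gene", "is_nontargeting"]))
    n_guides = len(lib.table)
    guide_gene = lib.table["gene"].to_numpy()

    ss = np.random.SeedSequence(config.seed)
    rng_lib, rng_counts = (np.random.default_rng(s) for s in ss.spawn(2))
    baseline = rng_lib.lognormal(0.0, config.library_skew_sdlog, n_guides)

    samples = []
    columns: dict[str, np.ndarray] = {}
    for r in range(config.n_t0_replicates):
        sid = f"T0_r{r + 1}"
        prob = baseline / baseline.sum()
        columns[sid] = _nb_sample(rng_counts, config.reads_per_sample * prob, config.dispersion)
        samples.append((sid, "T0", "T0", "T0", r + 1, True))
    for cond in config.conditions:
        mult = np.ones(n_guides)
        for g, eff in config.planted_effects.items():
            m = eff.get((cond.organ, cond.treatment))
            if m is not None:
                mult[guide_gene == g] = m
        abund = baseline * mult
        prob = abund / abund.sum()
        for r in range(cond.n_replicates):
            sid = f"{cond.organ}_{cond.treatment}_r{r + 1}"
            columns[sid] = _nb_sample(
                rng_counts, config.reads_per_sample * prob, config.dispersion
            )
            samples.append((sid, cond.organ, cond.treatment, cond.batch, r + 1, False))

    counts = pd.DataFrame(columns, index=lib.guide_ids)
    meta = pd.DataFrame(
        samples, columns=["sample_id", "organ", "treatment", "batch", "replicate", "is_t0"]
    )
    directions = {
        g: ("enriched" if max(eff.values()) > 1 else "depleted")
        for g, eff in config.planted_effects.items()
    }
    truth = SimTruth(
        planted_effects={g: dict(e) for g, e in config.planted_effects.items()},
        planted_directions=directions,
    )
    return lib, ScreenCounts(counts, meta), truth


# ---------------------------------------------------------------------------
# CROP-seq


@dataclass
class CropseqSimConfig:
    """Design of a simulated CROP-seq experiment.

    ``cluster_shift`` maps gene -> per-cluster additive log-fold shifts on
    the base cluster probabilities (renormalized per gene).  Each cell
    carries one true guide (Poisson UMIs at ``true_guide_umi_mean``) over
    an ambient Poisson background on every other guide; doublets carry a
    second true guide and are flagged only in the truth.
    """

    n_genes: int = 20
    guides_per_gene: int = 3
    n_nontargeting_guides: int = 10
    cells_per_guide: int = 50
    base_cluster_probs: Sequence[float] = (1 / 6,) * 6
    cluster_shift: Mapping[str, Sequence[float]] = field(default_factory=dict)
    ambient_rate: float = 0.2
    true_guide_umi_mean: float = 30.0
    doublet_rate: float = 0.03
    mito_beta_params: tuple[float, float] = (2.0, 38.0)
    umi_lognormal: tuple[float, float] = (np.log(10_000.0), 0.4)
    seed: int = 0


def simulate_cropseq(
    config: CropseqSimConfig,
) -> tuple[CellGuideCapture, pd.DataFrame, GuideLibrary, SimTruth]:
    """Simulate guide capture and cell annotations for a CROP-seq screen.

    Returns (capture, cell annotation table, guide library, truth).  The
    annotation includes the truth-derived cluster label, usable directly by
    the ranking stage in place of a clustering run.
    """
    base = np.asarray(config.base_cluster_probs, dtype=float)
    if abs(base.sum() - 1.0) > 1e-9 or (base < 0).any():
        raise ConfigurationError("base_cluster_probs must be a probability vector")
    if config.ambient_rate < 0 or config.true_guide_umi_mean <= 0:
        raise ConfigurationError("rates must be nonnegative")
    if not 0 <= config.doublet_rate <= 1:
        raise ConfigurationError("doublet_rate must be a probability")
    n_clusters = len(base)
    genes = [gene_name(i) for i in range(config.n_genes)]
    gene_set = set(genes)
    for g, shift in config.cluster_shift.items():
        if g not in gene_set:
            raise ConfigurationError(f"cluster_shift references unknown gene {g!r}")
        if len(shift) != n_clusters:
            raise ConfigurationError(f"cluster_shift for {g!r} has wrong length")

    rows = []
    for g in genes:
        for j in range(config.guides_per_gene):
            rows.append((f"{g}_g{j + 1}", g, False))
    for j in range(config.n_nontargeting_guides):
        rows.append((f"nt_{j + 1:03d}", NONTARGETING, True))
    lib = GuideLibrary(pd.DataFrame(rows, columns=["guide_id", "gene", "is_nontargeting"]))
    guide_ids = list(lib.guide_ids)
    guide_gene = lib.table["gene"].to_numpy()
    n_guides = len(guide_ids)

    probs_by_gene: dict[str, np.ndarray] = {NONTARGETING: base.copy()}
    for g in genes:
        shift = np.asarray(config.cluster_shift.get(g, np.zeros(n_clusters)), dtype=float)
        w = base * np.exp(shift)
        probs_by_gene[g] = w / w.sum()

    n_cells = n_guides * config.cells_per_guide
    true_guide_idx = np.repeat(np.arange(n_guides), config.cells_per_guide)
    ss = np.random.SeedSequence(config.seed)
    rng_cap, rng_doub, rng_clu, rng_qc = (np.random.default_rng(s) for s in ss.spawn(4))

    umis = rng_cap.poisson(config.ambient_rate, size=(n_cells, n_guides))
    umis[np.arange(n_cells), true_guide_idx] += rng_cap.poisson(
        config.true_guide_umi_mean, size=n_cells
    )
    is_doublet = rng_doub.random(n_cells) < config.doublet_rate
    second_idx = np.full(n_cells, -1)
    for i in np.flatnonzero(is_doublet):
        other = rng_doub.integers(0, n_guides - 1)
        if other >= true_guide_idx[i]:
            other += 1
        second_idx[i] = other
        umis[i, other] += rng_doub.poisson(config.true_guide_umi_mean)

    # cluster label from the (first) true guide's gene
    labels = np.empty(n_cells, dtype=int)
    for g, probs in probs_by_gene.items():
        mask = guide_gene[true_guide_idx] == g
        if mask.any():
            labels[mask] = rng_clu.choice(n_clusters, size=int(mask.sum()), p=probs)

    mu, sigma = config.umi_lognormal
    a, b = config.mito_beta_params
    cells = pd.DataFrame(
        {
            "cell": [f"cell{i + 1:06d}" for i in range(n_cells)],
            "sample": "s1",
            "total_umis": np.maximum(1, rng_qc.lognormal(mu, sigma, n_cells)).astype(int),
            "mito_fraction": rng_qc.beta(a, b, n_cells),
            "cluster": labels,
        }
    )
    capture = CellGuideCapture(
        sparse.csr_matrix(umis), list(cells["cell"]), guide_ids
    )
    cell_guides = [
        [guide_ids[true_guide_idx[i]]]
        + ([guide_ids[second_idx[i]]] if is_doublet[i] else [])
        for i in range(n_cells)
    ]
    truth = SimTruth(
        cell_guides=cell_guides,
        cell_doublet=list(map(bool, is_doublet)),
        gene_cluster_probs={g: p.copy() for g, p in probs_by_gene.items()},
    )
    return capture, cells, lib, truth


# ---------------------------------------------------------------------------
# SMLM localization fields


@dataclass(frozen=True)
class PlantedCluster:
    center: tuple[float, float]  # nm
    radius: float  # nm
    n_points: int


#: Default field: a 10x10 um ROI, 2,000 background localizations and three
#: well-separated dense discs of 40 localizations each.
DEFAULT_SMLM_CLUSTERS = (
    PlantedCluster((2500.0, 2500.0), 250.0, 40),
    PlantedCluster((5000.0, 7000.0), 250.0, 40),
    PlantedCluster((7500.0, 3500.0), 250.0, 40),
)


@dataclass
class SmlmSimConfig:
    """Homogeneous Poisson background plus planted uniform discs (nm)."""

    roi_width: float = 10_000.0
    roi_height: float = 10_000.0
    n_background: int = 2000
    clusters: Sequence[PlantedCluster] = DEFAULT_SMLM_CLUSTERS
    seed: int = 0


def simulate_localizations(config: SmlmSimConfig) -> tuple[LocalizationSet, SimTruth]:
    """Simulate a localization field; truth labels each point -1 (background)
    or the index of its planted cluster."""
    if config.n_background < 0 or any(c.n_points < 0 for c in config.clusters):
        raise ConfigurationError("counts must be >= 0")
    roi = box(0.0, 0.0, config.roi_width, config.roi_height)
    for k, c in enumerate(config.clusters):
        disc = Point(c.center).buffer(c.radius)
        if not roi.covers(disc):
            raise ConfigurationError(f"cluster {k} disc extends outside the ROI")

    rng = np.random.default_rng(config.seed)
    bg = rng.uniform(
        [0.0, 0.0], [config.roi_width, config.roi_height], size=(config.n_background, 2)
    )
    parts = [bg]
    labels = [np.full(config.n_background, -1)]
    for k, c in enumerate(config.clusters):
        r = c.radius * np.sqrt(rng.random(c.n_points))
        theta = rng.uniform(0, 2 * np.pi, c.n_points)
        pts = np.column_stack(
            [c.center[0] + r * np.cos(theta), c.center[1] + r * np.sin(theta)]
        )
        parts.append(pts)
        labels.append(np.full(c.n_points, k))
    points = np.vstack(parts) if parts else np.empty((0, 2))
    truth = SimTruth(point_labels=np.concatenate(labels))
    return LocalizationSet(points, roi), truth
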