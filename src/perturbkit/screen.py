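"""Pooled CRISPR screen enrichment analysis.

Implements the gene-level selection scoring used to nominate hits from a
multi-organ in vivo screen: nontargeting-control normalization of guide
counts, a per-guide location--scale batch adjustment, two independent
gene statistics (an order-statistic rank score with a permutation null,
and a mean log-fold-change effect with a nontargeting resampling null),
and the hit-distillation rule requiring both statistics to call a gene
enriched in at least one (organ, treatment) condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("perturbkit.screen")

#: Sentinel gene label for nontargeting control guides.
NONTARGETING = "non-targeting"

SAMPLE_COLUMNS = ["sample_id", "organ", "treatment", "batch", "replicate", "is_t0"]


@dataclass
class GuideLibrary:
    """Guide -> gene map with a nontargeting flag.

    ``table`` columns: ``guide_id``, ``gene``, ``is_nontargeting``.
    The library defines the guide universe for every screen statistic.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"guide_id", "gene", "is_nontargeting"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"library table missing columns: {sorted(missing)}")
        if self.table["guide_id"].duplicated().any():
            dup = self.table.loc[self.table["guide_id"].duplicated(), "guide_id"].iloc[0]
            raise ValueError(f"duplicate guide_id in library: {dup!r}")
        if len(self.table) == 0:
            raise ValueError("empty guide library")
        self.table = self.table.reset_index(drop=True)

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    @property
    def nontargeting_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_nontargeting"], "guide_id"])

    @property
    def genes(self) -> list[str]:
        sub = self.table.loc[~self.table["is_nontargeting"], "gene"]
        return sorted(sub.unique())

    def guides_of(self, gene: str) -> list[str]:
        return list(self.table.loc[self.table["gene"] == gene, "guide_id"])


@dataclass
class ScreenCounts:
    """Guides x samples integer counts with sample metadata.

    ``counts``: DataFrame indexed by guide_id, one column per sample.
    ``samples``: DataFrame with columns ``sample_id``, ``organ``,
    ``treatment``, ``batch``, ``replicate``, ``is_t0``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        meta_ids = list(self.samples["sample_id"])
        if set(meta_ids) != set(self.counts.columns):
            raise ValueError("sample metadata does not match count columns")
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate sample_id in metadata")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        self.samples = self.samples.reset_index(drop=True)

    @property
    def t0_samples(self) -> list[str]:
        return list(self.samples.loc[self.samples["is_t0"], "sample_id"])

    def conditions(self) -> list[tuple[str, str]]:
        """Distinct (organ, treatment) pairs among non-T0 samples."""
        sub = self.samples.loc[~self.samples["is_t0"], ["organ", "treatment"]]
        return sorted(set(map(tuple, sub.itertuples(index=False))))

    def condition_samples(self, organ: str, treatment: str) -> list[str]:
        m = self.samples
        sel = (~m["is_t0"]) & (m["organ"] == organ) & (m["treatment"] == treatment)
        return list(m.loc[sel, "sample_id"])


@dataclass
class GuideLFC:
    """Guide-level log2 fold changes vs the mean T0 reference."""

    values: pd.DataFrame  # guides x samples, same layout as ScreenCounts.counts
    samples: pd.DataFrame
    pseudocount: float

    @property
    def t0_samples(self) -> list[str]:
        return list(self.samples.loc[self.samples["is_t0"], "sample_id"])

    def conditions(self) -> list[tuple[str, str]]:
        sub = self.samples.loc[~self.samples["is_t0"], ["organ", "treatment"]]
        return sorted(set(map(tuple, sub.itertuples(index=False))))

    def condition_samples(self, organ: str, treatment: str) -> list[str]:
        m = self.samples
        sel = (~m["is_t0"]) & (m["organ"] == organ) & (m["treatment"] == treatment)
        return list(m.loc[sel, "sample_id"])

    def condition_mean(self, organ: str, treatment: str) -> pd.Series:
        """Per-guide LFC averaged over the condition's replicates."""
        cols = self.condition_samples(organ, treatment)
        if not cols:
            raise ValueError(f"no samples for condition ({organ}, {treatment})")
        return self.values[cols].mean(axis=1)


def sample_qc(
    counts: ScreenCounts, min_total_fraction: float = 0.1
) -> tuple[ScreenCounts, list[str]]:
    """Drop samples whose total count falls below a fraction of the median total.

    Returns the filtered table and the list of excluded sample ids.
    T0 samples are subject to the same rule.
    """
    if counts.counts.shape[1] == 0:
        raise ValueError("no samples")
    totals = counts.counts.sum(axis=0)
    threshold = min_total_fraction * float(np.median(totals.to_numpy()))
    keep = totals[totals >= threshold].index
    excluded = [s for s in counts.counts.columns if s not in set(keep)]
    if len(keep) == 0:
        raise ValueError("sample QC excluded every sample")
    for s in excluded:
        logger.warning(
            "sample_qc: excluding sample %s (total %d < %.1f)", s, totals[s], threshold
        )
    meta = counts.samples[counts.samples["sample_id"].isin(set(keep))]
    return ScreenCounts(counts.counts[list(keep)], meta.copy()), excluded


def normalize_counts(
    counts: ScreenCounts, library: GuideLibrary, pseudocount: float = 0.5
) -> GuideLFC:
    """Nontargeting median-of-ratios normalization and log2 fold change vs T0.

    Per-sample size factor: median over nontargeting guides of
    (count / per-guide geometric mean across samples); nontargeting guides
    with a zero count in any sample are excluded from the median, as in
    median-of-ratios normalization.  LFC uses a pseudocount added to the
    normalized counts on both sides of the ratio.
    """
    mat = counts.counts.reindex(library.guide_ids)
    if mat.isna().any().any():
        missing = mat.index[mat.isna().any(axis=1)][0]
        raise ValueError(f"count table is missing library guide {missing!r}")
    if set(counts.counts.index) != set(library.guide_ids):
        extra = sorted(set(counts.counts.index) - set(library.guide_ids))
        raise ValueError(f"count table contains guides not in library: {extra[:5]}")
    nt_ids = [g for g in library.nontargeting_ids if g in mat.index]
    if len(nt_ids) == 0:
        raise ValueError("library has no nontargeting guides; normalization impossible")
    if not counts.t0_samples:
        raise ValueError("no T0 reference samples")

    ntm = mat.loc[nt_ids].to_numpy(dtype=float)
    zero_samples = np.asarray(ntm.sum(axis=0) == 0).nonzero()[0]
    if zero_samples.size:
        bad = mat.columns[zero_samples[0]]
        raise ValueError(f"all nontargeting counts are zero in sample {bad!r}")
    all_pos = (ntm > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no nontargeting guide has nonzero counts in every sample; "
            "cannot form the geometric-mean reference"
        )
    ref = np.exp(np.log(ntm[all_pos]).mean(axis=1))
    ratios = ntm[all_pos] / ref[:, None]
    size_factors = np.median(ratios, axis=0)
    if (size_factors <= 0).any():
        bad = mat.columns[int(np.argmin(size_factors))]
        raise ValueError(f"nonpositive size factor for sample {bad!r}")

    norm = mat.to_numpy(dtype=float) / size_factors[None, :]
    t0_idx = [mat.columns.get_loc(s) for s in counts.t0_samples]
    t0_mean = norm[:, t0_idx].mean(axis=1)
    lfc = np.log2((norm + pseudocount) / (t0_mean[:, None] + pseudocount))
    values = pd.DataFrame(lfc, index=mat.index, columns=mat.columns)
    return GuideLFC(values, counts.samples.copy(), pseudocount)


def adjust_batch(lfc: GuideLFC, batches: Mapping[str, str] | None = None) -> GuideLFC:
    """Per-guide location--scale batch adjustment.

    Within each batch b, x' = (x - m_gb) * (s_g / s_gb) + m_g, where m/s are
    the per-guide mean/SD overall (g) and within batch (gb).  Scaling is
    skipped (location-only) when a batch has fewer than 3 samples or the
    within-batch SD is zero.  A simplified stand-in for empirical-Bayes
    batch correction.
    """
    meta = lfc.samples
    if batches is None:
        batch_of = dict(zip(meta["sample_id"], meta["batch"]))
    else:
        batch_of = dict(batches)
    labels = []
    for s in lfc.values.columns:
        if s not in batch_of or batch_of[s] is None or (
            isinstance(batch_of[s], float) and np.isnan(batch_of[s])
        ):
            raise ValueError(f"sample {s!r} has no batch label")
        labels.append(batch_of[s])
    labels = np.asarray(labels, dtype=object)

    vals = lfc.values.to_numpy(dtype=float)
    out = vals.copy()
    m_g = vals.mean(axis=1)
    s_g = vals.std(axis=1, ddof=1) if vals.shape[1] > 1 else np.zeros(vals.shape[0])
    for b in pd.unique(labels):
        idx = labels == b
        xb = vals[:, idx]
        m_gb = xb.mean(axis=1)
        n_b = int(idx.sum())
        if n_b >= 3:
            s_gb = xb.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(s_gb > 0, s_g / np.where(s_gb > 0, s_gb, 1.0), 1.0)
        else:
            scale = np.ones(vals.shape[0])
        out[:, idx] = (xb - m_gb[:, None]) * scale[:, None] + m_g[:, None]
    values = pd.DataFrame(out, index=lfc.values.index, columns=lfc.values.columns)
    return GuideLFC(values, lfc.samples.copy(), lfc.pseudocount)


# ---------------------------------------------------------------------------
# rank (order-statistic) score


def _rank_guides(mean_lfc: pd.Series, direction: str) -> pd.Series:
    """1-based guide ranks; rank 1 = strongest in the requested direction.

    Ties broken by guide_id lexical order (deterministic).
    """
    if direction not in ("enriched", "depleted"):
        raise ValueError(f"direction must be 'enriched' or 'depleted', got {direction!r}")
    df = pd.DataFrame({"v": mean_lfc.to_numpy(), "g": mean_lfc.index})
    asc = direction == "depleted"
    order = df.sort_values(["v", "g"], ascending=[asc, True]).index
    ranks = pd.Series(0, index=mean_lfc.index, dtype=int)
    ranks.iloc[order] = np.arange(1, len(df) + 1)
    return ranks


def _order_statistic_score(
    sorted_ranks: np.ndarray, k: int, n_total: int, cutoff: float
) -> np.ndarray:
    """-log10 binomial tail score from sorted 1-based guide ranks.

    ``sorted_ranks``: array (..., k).  For the j-th best rank r_j within the
    top fraction, the candidate score is -log10 P[X >= j], X ~ Binom(k, r_j/N);
    the score is the best candidate, or 0 if no rank is in the top fraction.
    """
    j = np.arange(1, k + 1)
    p = sorted_ranks / n_total
    tail = stats.binom.sf(j - 1, k, p)
    with np.errstate(divide="ignore"):
        cand = -np.log10(tail)
    cand = np.where(sorted_ranks <= cutoff + 1e-9, cand, -np.inf)
    best = cand.max(axis=-1)
    return np.where(np.isfinite(best), best, 0.0)


def _sample_rank_sets(
    rng: np.random.Generator, n_perm: int, n_total: int, k: int
) -> np.ndarray:
    """(n_perm, k) sorted 1-based ranks drawn uniformly without replacement."""
    u = rng.random((n_perm, n_total))
    picks = np.argpartition(u, k - 1, axis=1)[:, :k]
    return np.sort(picks + 1, axis=1)


def gene_score_rank(
    lfc: GuideLFC,
    library: GuideLibrary,
    condition: tuple[str, str],
    direction: str = "enriched",
    top_fraction: float = 0.10,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Order-statistic gene score with a guide-permutation p-value.

    Guides are ranked by their mean LFC over the condition's replicates
    (descending for ``enriched``, ascending for ``depleted``) among all N
    library guides.  The gene score is the strongest -log10 binomial tail
    over its guides that fall within the top ``top_fraction`` of the ranking;
    the permutation p-value redraws the gene's guide ranks uniformly.

    Returns a DataFrame with columns ``gene``, ``score_rank``, ``p_rank``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    organ, treatment = condition
    mean_lfc = lfc.condition_mean(organ, treatment)
    ranks = _rank_guides(mean_lfc, direction)
    n_total = len(ranks)
    cutoff = top_fraction * n_total

    rng = np.random.default_rng(seed)
    guides_by_gene = (
        library.table.loc[~library.table["is_nontargeting"]]
        .groupby("gene")["guide_id"]
        .apply(list)
    )
    null_by_k: dict[int, np.ndarray] = {}
    rows = []
    for gene in sorted(guides_by_gene.index):
        gids = [g for g in guides_by_gene[gene] if g in ranks.index]
        k = len(gids)
        if k == 0:
            logger.warning("gene_score_rank: gene %s has no guides, excluded", gene)
            continue
        r = np.sort(ranks.loc[gids].to_numpy())
        score = float(_order_statistic_score(r[None, :], k, n_total, cutoff)[0])
        if k not in null_by_k:
            sets = _sample_rank_sets(rng, n_perm, n_total, k)
            null_by_k[k] = _order_statistic_score(sets, k, n_total, cutoff)
        null = null_by_k[k]
        p = (1 + int(np.count_nonzero(null >= score - 1e-12))) / (n_perm + 1)
        rows.append((gene, score, p))
    return pd.DataFrame(rows, columns=["gene", "score_rank", "p_rank"])


# ---------------------------------------------------------------------------
# effect (mean-LFC) score


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def gene_score_effect(
    lfc: GuideLFC,
    library: GuideLibrary,
    condition: tuple[str, str],
    n_resample: int = 10_000,
    seed: int = 0,
    variance_stabilize: bool = True,
) -> pd.DataFrame:
    """Mean-LFC gene effect with a nontargeting resampling null.

    The effect is the mean guide LFC over the condition's replicates; the
    null distribution resamples k guides with replacement from the
    nontargeting guide LFCs.  With ``variance_stabilize`` (default) the
    nontargeting deviations are rescaled so their robust spread matches the
    robust spread of all guides in the condition: with few control guides
    the raw control spread is an unstable width estimate, and under the
    screen's sparse-hit assumption the all-guide MAD is a better one.
    Two-sided p-values (with a +1 correction) compare |effect - mu0|
    against the null, mu0 being the mean nontargeting LFC.  Each null draw
    is the deviation of a k-guide resample mean from an independent
    bootstrap mean of the whole control pool, so the null carries the same
    centre uncertainty as the observed contrast.  BH adjustment is applied
    across genes.

    Returns columns ``gene``, ``effect_mean_lfc``, ``p_effect``,
    ``fdr_effect``, ``direction``.
    """
    organ, treatment = condition
    mean_lfc = lfc.condition_mean(organ, treatment)
    nt_ids = [g for g in library.nontargeting_ids if g in mean_lfc.index]
    if len(nt_ids) < 10:
        raise ValueError(f"need >= 10 nontargeting guides, have {len(nt_ids)}")
    nt_vals = mean_lfc.loc[nt_ids].to_numpy()
    mu0 = float(nt_vals.mean())
    if variance_stabilize:
        # robust spread on the all-guide side (hits may live there); plain SD
        # on the control side, which is null by construction
        s_all = _robust_sd(mean_lfc.to_numpy())
        s_nt = float(nt_vals.std(ddof=1))
        if s_all > 0 and s_nt > 0:
            nt_vals = mu0 + (nt_vals - mu0) * (s_all / s_nt)

    rng = np.random.default_rng(seed)
    n_nt = len(nt_vals)
    centre_idx = rng.integers(0, n_nt, size=(n_resample, n_nt))
    null_centres = nt_vals[centre_idx].mean(axis=1)
    guides_by_gene = (
        library.table.loc[~library.table["is_nontargeting"]]
        .groupby("gene")["guide_id"]
        .apply(list)
    )
    null_dev_by_k: dict[int, np.ndarray] = {}
    rows = []
    for gene in sorted(guides_by_gene.index):
        gids = [g for g in guides_by_gene[gene] if g in mean_lfc.index]
        k = len(gids)
        if k == 0:
            logger.warning("gene_score_effect: gene %s has no guides, excluded", gene)
            continue
        effect = float(mean_lfc.loc[gids].mean())
        if k not in null_dev_by_k:
            idx = rng.integers(0, n_nt, size=(n_resample, k))
            null_means = nt_vals[idx].mean(axis=1)
            null_dev_by_k[k] = np.sort(np.abs(null_means - null_centres))
        dev = null_dev_by_k[k]
        d = abs(effect - mu0)
        n_ge = len(dev) - int(np.searchsorted(dev, d, side="left"))
        p = (1 + n_ge) / (n_resample + 1)
        direction = "enriched" if effect >= mu0 else "depleted"
        rows.append((gene, effect, p, direction))
    df = pd.DataFrame(rows, columns=["gene", "effect_mean_lfc", "p_effect", "direction"])
    if len(df):
        df["fdr_effect"] = multipletests(df["p_effect"].to_numpy(), method="fdr_bh")[1]
    else:
        df["fdr_effect"] = []
    return df[["gene", "effect_mean_lfc", "p_effect", "fdr_effect", "direction"]]


def score_conditions(
    lfc: GuideLFC,
    library: GuideLibrary,
    top_fraction: float = 0.10,
    n_perm: int = 1000,
    n_resample: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Both gene statistics for every (organ, treatment) condition.

    Per gene the reported rank score is the one computed in the direction of
    the gene's effect, so the two statistics always describe the same tail.
    Returns one row per gene x condition with columns ``gene``, ``organ``,
    ``treatment``, ``score_rank``, ``p_rank``, ``effect_mean_lfc``,
    ``p_effect``, ``fdr_effect``, ``direction``.
    """
    ss = np.random.SeedSequence(seed)
    frames = []
    for (organ, treatment), child in zip(
        lfc.conditions(), ss.spawn(len(lfc.conditions()))
    ):
        s_rank_e, s_rank_d, s_eff = (int(c.generate_state(1)[0] % 2**31) for c in child.spawn(3))
        eff = gene_score_effect(lfc, library, (organ, treatment), n_resample, seed=s_eff)
        rank_e = gene_score_rank(
            lfc, library, (organ, treatment), "enriched", top_fraction, n_perm, seed=s_rank_e
        ).set_index("gene")
        rank_d = gene_score_rank(
            lfc, library, (organ, treatment), "depleted", top_fraction, n_perm, seed=s_rank_d
        ).set_index("gene")
        eff = eff.set_index("gene")
        use_e = eff["direction"] == "enriched"
        eff["score_rank"] = np.where(
            use_e, rank_e.loc[eff.index, "score_rank"], rank_d.loc[eff.index, "score_rank"]
        )
        eff["p_rank"] = np.where(
            use_e, rank_e.loc[eff.index, "p_rank"], rank_d.loc[eff.index, "p_rank"]
        )
        eff["organ"] = organ
        eff["treatment"] = treatment
        frames.append(eff.reset_index())
    out = pd.concat(frames, ignore_index=True)
    return out[
        [
            "gene",
            "organ",
            "treatment",
            "score_rank",
            "p_rank",
            "effect_mean_lfc",
            "p_effect",
            "fdr_effect",
            "direction",
        ]
    ]


def distill_hits(
    scores: pd.DataFrame, p_rank_max: float = 0.05, fdr_effect_max: float = 0.05
) -> pd.DataFrame:
    """Distill multi-condition hits: both statistics significant and enriched
    in at least one (organ, treatment) condition.

    Returns one row per gene with columns ``gene``, ``hit``,
    ``supporting_conditions`` (list of (organ, treatment)), ``multi_site``
    (supported in more than one organ).
    """
    required = {"gene", "organ", "treatment", "p_rank", "fdr_effect", "direction"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    sup = scores[
        (scores["direction"] == "enriched")
        & (scores["p_rank"] <= p_rank_max)
        & (scores["fdr_effect"] <= fdr_effect_max)
    ]
    rows = []
    for gene in sorted(scores["gene"].unique()):
        conds = sorted(
            set(
                map(
                    tuple,
                    sup.loc[sup["gene"] == gene, ["organ", "treatment"]].itertuples(
                        index=False
                    ),
                )
            )
        )
        organs = {o for o, _ in conds}
        rows.append((gene, len(conds) > 0, conds, len(organs) > 1))
    return pd.DataFrame(rows, columns=["gene", "hit", "supporting_conditions", "multi_site"])


def tissue_distribution(hits: pd.DataFrame) -> dict:
    """Per-organ hit counts and the fraction of hits supported in >1 organ.

    With no hits the fraction is reported as 0.0 with ``undefined=True``.
    """
    organ_counts: dict[str, int] = {}
    hit_rows = hits[hits["hit"]]
    for conds in hit_rows["supporting_conditions"]:
        for organ in {o for o, _ in conds}:
            organ_counts[organ] = organ_counts.get(organ, 0) + 1
    n_hits = int(hit_rows.shape[0])
    if n_hits == 0:
        return {"organ_counts": {}, "multi_site_fraction": 0.0, "undefined": True}
    frac = float(hit_rows["multi_site"].sum()) / n_hits
    return {
        "organ_counts": dict(sorted(organ_counts.items())),
        "multi_site_fraction": frac,
        "undefined": False,
    }
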