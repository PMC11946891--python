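"""Screen enrichment: normalization, batch adjustment, gene statistics, distillation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import perturbkit as pk
from perturbkit.screen import NONTARGETING, GuideLFC, ScreenCounts, _rank_guides

from conftest import make_library, make_lfc, one_condition_samples


# ---------------------------------------------------------------------------
# sample QC


def _screen_counts(totals, n_guides=4):
    """Counts table with the requested per-sample totals spread over guides."""
    lib = make_library({"geneA": n_guides - 2}, 2)
    cols = {}
    rows = []
    for i, t in enumerate(totals):
        sid = f"s{i}"
        per = t // n_guides
        cols[sid] = [per] * (n_guides - 1) + [t - per * (n_guides - 1)]
        rows.append((sid, "tumour", "IgG", "b1", i, i == 0))
    counts = pd.DataFrame(cols, index=lib.guide_ids)
    meta = pd.DataFrame(
        rows, columns=["sample_id", "organ", "treatment", "batch", "replicate", "is_t0"]
    )
    return ScreenCounts(counts, meta)


def test_sample_qc_drops_only_the_shallow_sample():
    sc = _screen_counts([100_000, 98_000, 102_000, 99_000, 5_000])
    kept, excluded = pk.sample_qc(sc, min_total_fraction=0.1)
    assert excluded == ["s4"]
    assert kept.counts.shape[1] == 4


def test_sample_qc_equal_totals_keeps_everything():
    sc = _screen_counts([50_000] * 5)
    kept, excluded = pk.sample_qc(sc)
    assert excluded == [] and kept.counts.shape[1] == 5


def test_sample_qc_single_sample_passes():
    sc = _screen_counts([50_000])
    kept, excluded = pk.sample_qc(sc)
    assert excluded == [] and kept.counts.shape[1] == 1


# ---------------------------------------------------------------------------
# normalization


def test_normalize_identity_and_scale_invariance(toy_counts):
    lib, sc = toy_counts
    # T0 column vs itself: all lfc 0
    same = ScreenCounts(
        pd.DataFrame({"T0_r1": sc.counts["T0_r1"], "tumour_anti-PD-1_r1": sc.counts["T0_r1"]},
                     index=sc.counts.index),
        sc.samples,
    )
    lfc = pk.normalize_counts(same, lib)
    assert np.allclose(lfc.values.to_numpy(), 0.0, atol=1e-12)
    # doubling every count of the non-T0 sample: pure library-size change, lfc 0
    doubled = ScreenCounts(
        pd.DataFrame({"T0_r1": sc.counts["T0_r1"], "tumour_anti-PD-1_r1": 2 * sc.counts["T0_r1"]},
                     index=sc.counts.index),
        sc.samples,
    )
    lfc = pk.normalize_counts(doubled, lib)
    assert np.allclose(lfc.values.to_numpy(), 0.0, atol=1e-12)


def test_normalize_toy_table_matches_hand_computation(toy_counts):
    lib, sc = toy_counts
    lfc = pk.normalize_counts(sc, lib, pseudocount=0.5)
    # hand computation: nt geometric means sqrt(100*200), sqrt(400*800);
    # both nt ratios agree within each sample -> size factors 1/sqrt(2), sqrt(2)
    sf_t0, sf_s1 = 100 / math.sqrt(100 * 200), 200 / math.sqrt(100 * 200)
    norm_t0 = np.array([100, 200, 100, 400]) / sf_t0
    norm_s1 = np.array([400, 200, 200, 800]) / sf_s1
    expected_s1 = np.log2((norm_s1 + 0.5) / (norm_t0 + 0.5))
    assert np.allclose(lfc.values["tumour_anti-PD-1_r1"].to_numpy(), expected_s1, atol=1e-12)
    assert np.allclose(lfc.values["T0_r1"].to_numpy(), 0.0, atol=1e-12)


def test_normalize_median_nontargeting_ratio_is_one():
    lib, sc, _ = pk.simulate_screen(pk.ScreenSimConfig(n_genes=30, seed=5))
    mat = sc.counts.reindex(lib.guide_ids).to_numpy(float)
    nt_mask = lib.table["is_nontargeting"].to_numpy()
    ntm = mat[nt_mask]
    ref = np.exp(np.log(ntm).mean(axis=1))
    sf = np.median(ntm / ref[:, None], axis=0)
    assert np.allclose(np.median((ntm / sf) / ref[:, None], axis=0), 1.0, atol=1e-9)


def test_normalize_scale_invariance_of_single_sample():
    """Scaling one sample's raw counts leaves LFC unchanged (exact without
    pseudocount; near-exact at the default pseudocount)."""
    lib, sc, _ = pk.simulate_screen(pk.ScreenSimConfig(n_genes=30, seed=7))
    scaled_counts = sc.counts.copy()
    target = sc.conditions()[0]
    col = sc.condition_samples(*target)[0]
    scaled_counts[col] = scaled_counts[col] * 7
    scaled = ScreenCounts(scaled_counts, sc.samples)
    a = pk.normalize_counts(sc, lib, pseudocount=0.0).values
    b = pk.normalize_counts(scaled, lib, pseudocount=0.0).values
    assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)
    a = pk.normalize_counts(sc, lib, pseudocount=0.5).values
    b = pk.normalize_counts(scaled, lib, pseudocount=0.5).values
    assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-3


def test_normalize_errors_on_all_zero_nontargeting():
    lib = make_library({"geneA": 2}, 2)
    counts = pd.DataFrame(
        {"T0_r1": [10, 10, 5, 5], "tumour_anti-PD-1_r1": [10, 10, 0, 0]},
        index=lib.guide_ids,
    )
    sc = ScreenCounts(counts, one_condition_samples(1))
    with pytest.raises(ValueError, match="tumour_anti-PD-1_r1"):
        pk.normalize_counts(sc, lib)


# ---------------------------------------------------------------------------
# batch adjustment


def _lfc_with_batches(values, batches):
    n_guides, n_samples = values.shape
    rows = [
        (f"s{i}", "tumour", "IgG", batches[i], i, False) for i in range(n_samples)
    ]
    meta = pd.DataFrame(
        rows, columns=["sample_id", "organ", "treatment", "batch", "replicate", "is_t0"]
    )
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(n_guides)],
                      columns=[f"s{i}" for i in range(n_samples)])
    return GuideLFC(df, meta, 0.5)


def test_adjust_batch_single_batch_is_identity():
    rng = np.random.default_rng(0)
    lfc = _lfc_with_batches(rng.normal(size=(5, 4)), ["b1"] * 4)
    out = pk.adjust_batch(lfc)
    assert np.allclose(out.values.to_numpy(), lfc.values.to_numpy(), atol=1e-12)


def test_adjust_batch_removes_constant_offset():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(6, 8))
    offset = rng.normal(size=(6, 1))
    vals = base.copy()
    vals[:, 4:] = base[:, 4:] + offset  # batch 2 shifted per guide
    lfc = _lfc_with_batches(vals, ["b1"] * 4 + ["b2"] * 4)
    out = pk.adjust_batch(lfc).values.to_numpy()
    m1 = out[:, :4].mean(axis=1)
    m2 = out[:, 4:].mean(axis=1)
    assert np.allclose(m1, m2, atol=1e-9)


def test_adjust_batch_singleton_batch_gets_location_only():
    vals = np.array([[0.0, 2.0, 4.0, 10.0]])
    lfc = _lfc_with_batches(vals, ["b1", "b1", "b1", "b2"])
    out = pk.adjust_batch(lfc).values.to_numpy()[0]
    # singleton batch: x' = x - m_gb + m_g = 10 - 10 + 4 = 4 (no scaling)
    assert out[3] == pytest.approx(4.0)


def test_adjust_batch_unknown_label_errors():
    lfc = _lfc_with_batches(np.zeros((2, 2)), ["b1", "b1"])
    with pytest.raises(ValueError, match="s1"):
        pk.adjust_batch(lfc, batches={"s0": "b1", "s1": None})


# ---------------------------------------------------------------------------
# rank (order-statistic) score


def _lfc_with_gene_at_ranks(ranks, n_total, k, n_reps=1):
    """One gene with k guides placed at the given 1-based ranks among n_total."""
    lib = make_library({"geneA": k}, n_total - k)
    vals = np.zeros(n_total)
    # descending values by rank: rank r gets value n_total - r
    order = sorted(set(ranks))
    assert len(order) == k
    gene_positions = list(range(k))
    taken = set(ranks)
    free_ranks = [r for r in range(1, n_total + 1) if r not in taken]
    guide_rank = {}
    for gid, r in zip([f"geneA_g{j+1}" for j in range(k)], ranks):
        guide_rank[gid] = r
    for gid, r in zip([f"nt_{j+1:03d}" for j in range(n_total - k)], free_ranks):
        guide_rank[gid] = r
    guide_order = list(lib.guide_ids)
    values = {f"tumour_anti-PD-1_r{i+1}": [n_total - guide_rank[g] for g in guide_order]
              for i in range(n_reps)}
    meta = one_condition_samples(n_reps)
    values["T0_r1"] = [0.0] * n_total
    return lib, make_lfc(values, meta, guide_order)


def _binom_tail(j, k, p):
    """P[X >= j], X ~ Binom(k, p), by explicit summation (independent oracle)."""
    return sum(math.comb(k, x) * p**x * (1 - p) ** (k - x) for x in range(j, k + 1))


def _enumeration_score(ranks, k, n_total, cutoff):
    best = 0.0
    for j, r in enumerate(sorted(ranks), start=1):
        if r <= cutoff + 1e-9:
            best = max(best, -math.log10(_binom_tail(j, k, r / n_total)))
    return best


def test_rank_score_matches_exact_binomial_tail():
    """3 guides at ranks 1,2,3 of 100: score -log10 P[Binom(3,0.03) >= 3]."""
    lib, lfc = _lfc_with_gene_at_ranks([1, 2, 3], 100, 3)
    out = pk.gene_score_rank(lfc, lib, ("tumour", "anti-PD-1"), n_perm=200, seed=0)
    assert out.loc[0, "score_rank"] == pytest.approx(-math.log10(0.03**3), abs=1e-9)
    assert out.loc[0, "score_rank"] == pytest.approx(4.5686, abs=1e-3)
    assert out.loc[0, "p_rank"] >= 1 / 201


def test_rank_score_zero_outside_top_fraction():
    lib, lfc = _lfc_with_gene_at_ranks([50, 60, 70], 100, 3)
    out = pk.gene_score_rank(lfc, lib, ("tumour", "anti-PD-1"), n_perm=200, seed=0)
    assert out.loc[0, "score_rank"] == 0.0
    assert out.loc[0, "p_rank"] > 0.9


@pytest.mark.parametrize("ranks", [(1, 2, 3), (1, 5, 9), (2, 4, 6), (3, 7, 11)])
def test_rank_permutation_p_matches_exhaustive_enumeration(ranks):
    """N=12, k=3: permutation p agrees with enumeration over all C(12,3)
    placements within 3 Monte-Carlo standard errors."""
    n_total, k, n_perm, top_fraction = 12, 3, 10_000, 0.5
    cutoff = top_fraction * n_total
    obs = _enumeration_score(ranks, k, n_total, cutoff)
    all_scores = [
        _enumeration_score(c, k, n_total, cutoff)
        for c in itertools.combinations(range(1, n_total + 1), k)
    ]
    p_exact = sum(s >= obs - 1e-12 for s in all_scores) / len(all_scores)

    lib, lfc = _lfc_with_gene_at_ranks(list(ranks), n_total, k)
    out = pk.gene_score_rank(
        lfc, lib, ("tumour", "anti-PD-1"), top_fraction=top_fraction,
        n_perm=n_perm, seed=1,
    )
    se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
    assert abs(out.loc[0, "p_rank"] - p_exact) <= 3 * se + 2 / n_perm


def test_rank_direction_depleted_reverses_ordering():
    lib, lfc = _lfc_with_gene_at_ranks([1, 2, 3], 100, 3)
    out = pk.gene_score_rank(lfc, lib, ("tumour", "anti-PD-1"), "depleted",
                             n_perm=200, seed=0)
    assert out.loc[0, "score_rank"] == 0.0  # top enriched guides are bottom depleted


def test_guide_ranking_ties_broken_lexically():
    s = pd.Series([1.0, 1.0, 0.0], index=["b", "a", "c"])
    r = _rank_guides(s, "enriched")
    assert r["a"] == 1 and r["b"] == 2 and r["c"] == 3


# ---------------------------------------------------------------------------
# effect score


def _lfc_explicit(gene_vals, nt_vals):
    k, n_nt = len(gene_vals), len(nt_vals)
    lib = make_library({"geneA": k}, n_nt)
    guide_order = list(lib.guide_ids)
    meta = one_condition_samples(1)
    values = {
        "T0_r1": [0.0] * (k + n_nt),
        "tumour_anti-PD-1_r1": list(gene_vals) + list(nt_vals),
    }
    return lib, make_lfc(values, meta, guide_order)


def test_effect_p_degenerate_null_is_minimal():
    """All-zero nontargeting LFC and a clear effect: p = 1/(n_resample+1)."""
    lib, lfc = _lfc_explicit([2.0, 2.0, 2.0], [0.0] * 12)
    out = pk.gene_score_effect(lfc, lib, ("tumour", "anti-PD-1"), n_resample=1000, seed=0)
    assert out.loc[0, "p_effect"] == pytest.approx(1 / 1001)
    assert out.loc[0, "direction"] == "enriched"


def test_effect_p_is_one_when_guides_equal_nt_mean():
    nt = [0.1, -0.1, 0.3, -0.3, 0.2, -0.2, 0.15, -0.15, 0.05, -0.05]
    lib, lfc = _lfc_explicit([0.0, 0.0, 0.0], nt)  # nt mean is exactly 0
    out = pk.gene_score_effect(lfc, lib, ("tumour", "anti-PD-1"), n_resample=500, seed=0)
    assert out.loc[0, "p_effect"] == pytest.approx(1.0)


def test_effect_requires_ten_nontargeting_guides():
    lib, lfc = _lfc_explicit([1.0], [0.0] * 5)
    with pytest.raises(ValueError, match="nontargeting"):
        pk.gene_score_effect(lfc, lib, ("tumour", "anti-PD-1"))


def _bh_oracle(pvals):
    """Independent Benjamini-Hochberg: q_i = min_{j>=i} p_(j) * m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, pvals[i] * m / (pos + 1))
        q[i] = running
    return q


def test_bh_hand_example():
    from statsmodels.stats.multitest import multipletests

    p = [0.01, 0.02, 0.03, 0.5]
    q = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)
    assert np.allclose(q, _bh_oracle(p), atol=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
def test_bh_matches_brute_force_on_random_p_vectors(pvals):
    from statsmodels.stats.multitest import multipletests

    q = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(q, _bh_oracle(pvals), atol=1e-12)


# ---------------------------------------------------------------------------
# distillation and tissue distribution


def _score_row(gene, organ, treatment, p_rank, fdr, direction="enriched"):
    return {
        "gene": gene, "organ": organ, "treatment": treatment, "score_rank": 1.0,
        "p_rank": p_rank, "effect_mean_lfc": 1.0, "p_effect": fdr, "fdr_effect": fdr,
        "direction": direction,
    }


def test_distill_single_supporting_condition():
    scores = pd.DataFrame([
        _score_row("geneA", "liver", "anti-PD-1", 0.01, 0.01),
        _score_row("geneA", "lung", "anti-PD-1", 0.5, 0.5),
    ])
    hits = pk.distill_hits(scores)
    row = hits.iloc[0]
    assert bool(row["hit"]) and row["supporting_conditions"] == [("liver", "anti-PD-1")]
    assert not row["multi_site"]


def test_distill_requires_both_statistics():
    scores = pd.DataFrame([
        _score_row("geneA", "liver", "anti-PD-1", 0.01, 0.2),
        _score_row("geneA", "lung", "anti-PD-1", 0.01, 0.2),
    ])
    assert not pk.distill_hits(scores)["hit"].any()


def test_distill_depleted_genes_are_never_hits():
    scores = pd.DataFrame([
        _score_row("geneA", "liver", "anti-PD-1", 0.001, 0.001, direction="depleted"),
    ])
    assert not pk.distill_hits(scores)["hit"].any()


def test_distill_multi_organ_support_sets_multi_site():
    scores = pd.DataFrame([
        _score_row("geneA", "liver", "anti-PD-1", 0.01, 0.01),
        _score_row("geneA", "lung", "anti-PD-1", 0.01, 0.01),
    ])
    hits = pk.distill_hits(scores)
    assert bool(hits.iloc[0]["multi_site"])


def test_tissue_distribution_fraction_and_empty_flag():
    hits = pd.DataFrame({
        "gene": [f"g{i}" for i in range(10)],
        "hit": [True] * 10,
        "supporting_conditions": [[("liver", "anti-PD-1"), ("lung", "anti-PD-1")]] * 2
        + [[("liver", "anti-PD-1")]] * 8,
        "multi_site": [True] * 2 + [False] * 8,
    })
    dist = pk.tissue_distribution(hits)
    assert dist["multi_site_fraction"] == pytest.approx(0.2)
    assert dist["organ_counts"] == {"liver": 10, "lung": 2}
    empty = pk.tissue_distribution(hits.assign(hit=False))
    assert empty["multi_site_fraction"] == 0.0 and empty["undefined"]


# ---------------------------------------------------------------------------
# null calibration of the p-values


def test_null_pvalues_are_not_anticonservative():
    """Zero-effect screen: p_rank (fixed direction) and the two-sided
    p_effect are stochastically >= uniform.

    Tested with a one-sided KS statistic D+ = sup(ECDF - diagonal) per
    condition: under exact uniformity at n_genes = 200, D+ itself exceeds
    0.05 with probability ~0.37, so the assertion uses the KS bound at
    alpha = 0.01 (anti-conservative p-values fail it, sampling noise does
    not)."""
    from scipy.stats import kstest

    lib, counts, _ = pk.simulate_screen(pk.ScreenSimConfig(seed=0))
    lfc = pk.normalize_counts(counts, lib)
    for cond in lfc.conditions():
        rank = pk.gene_score_rank(lfc, lib, cond, "enriched", n_perm=500, seed=1)
        eff = pk.gene_score_effect(lfc, lib, cond, n_resample=2000, seed=2)
        for col, p in (("p_rank", rank["p_rank"]), ("p_effect", eff["p_effect"])):
            res = kstest(p.to_numpy(), "uniform", alternative="greater")
            assert res.pvalue > 0.01, (cond, col, res)
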