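import numpy as np
import pandas as pd
import pytest

from perturbkit.screen import NONTARGETING, GuideLibrary, GuideLFC, ScreenCounts


def make_library(genes: dict[str, int], n_nt: int) -> GuideLibrary:
    """Library with the given gene -> guide-count map plus nontargeting guides."""
    rows = []
    for g, k in genes.items():
        for j in range(k):
            rows.append((f"{g}_g{j + 1}", g, False))
    for j in range(n_nt):
        rows.append((f"nt_{j + 1:03d}", NONTARGETING, True))
    return GuideLibrary(pd.DataFrame(rows, columns=["guide_id", "gene", "is_nontargeting"]))


def make_lfc(values: dict[str, list[float]], samples: pd.DataFrame,
             guide_order: list[str], pseudocount: float = 0.5) -> GuideLFC:
    """GuideLFC from explicit per-sample guide values (test construction)."""
    df = pd.DataFrame(values, index=guide_order)
    return GuideLFC(df, samples, pseudocount)


def one_condition_samples(n_reps: int = 1, organ: str = "tumour",
                          treatment: str = "anti-PD-1") -> pd.DataFrame:
    rows = [("T0_r1", "T0", "T0", "T0", 1, True)]
    for r in range(n_reps):
        rows.append((f"{organ}_{treatment}_r{r + 1}", organ, treatment, organ, r + 1, False))
    return pd.DataFrame(
        rows, columns=["sample_id", "organ", "treatment", "batch", "replicate", "is_t0"]
    )


@pytest.fixture
def toy_counts() -> tuple[GuideLibrary, ScreenCounts]:
    """4-guide, 2-sample table (2 targeting, 2 nontargeting)."""
    lib = make_library({"geneA": 2}, 2)
    counts = pd.DataFrame(
        {"T0_r1": [100, 200, 100, 400], "tumour_anti-PD-1_r1": [400, 200, 200, 800]},
        index=["geneA_g1", "geneA_g2", "nt_001", "nt_002"],
    )
    meta = one_condition_samples(1)
    return lib, ScreenCounts(counts, meta)
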