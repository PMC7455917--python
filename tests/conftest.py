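"""Shared fixtures: small synthetic worlds generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import panelmeth as pm
from panelmeth import calling


@pytest.fixture(scope="session")
def small_world():
    """A noisy little cohort exercising duplicates, improper pairs and errors."""
    panel, reference = pm.generate_panel(5, (1, 2), (200, 400), seed=11)
    truth = pm.generate_cohort_truth(panel, n_samples=5, seed=12)
    reads = pm.generate_reads(
        truth, panel, reference, mean_depth=50, conversion_eff=0.99,
        seq_error=0.002, dup_rate=0.08, improper_frac=0.05, seed=13,
    )
    return {"panel": panel, "reference": reference, "truth": truth, "reads": reads}


@pytest.fixture(scope="session")
def clean_world():
    """Perfect conversion, no error/duplicates: per-site ratios are exact
    allele fractions."""
    panel, reference = pm.generate_panel(4, (1, 1), (200, 300), seed=21)
    truth = pm.generate_cohort_truth(panel, n_samples=4, jitter_sd=0.0, seed=22)
    reads = pm.generate_reads(
        truth, panel, reference, mean_depth=60, conversion_eff=1.0,
        seq_error=0.0, dup_rate=0.0, improper_frac=0.0, unmapped_frac=0.0, seed=23,
    )
    return {"panel": panel, "reference": reference, "truth": truth, "reads": reads}


@pytest.fixture(scope="session")
def called_sites(small_world):
    """Filtered per-sample CpG site tables for the noisy cohort."""
    panel, reference = small_world["panel"], small_world["reference"]
    out = {}
    for sample, pairs in small_world["reads"].items():
        filtered = calling.preprocess_reads(pairs)
        target = [p for p in filtered if p.chrom != panel.lambda_contig]
        out[sample] = calling.call_methylation(target, reference, panel)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)


def random_matrix(rng, n_regions=20, n_samples=10, missing_frac=0.0):
    arr = rng.uniform(0, 1, size=(n_regions, n_samples))
    if missing_frac:
        mask = rng.uniform(size=arr.shape) < missing_frac
        # keep at least one observed value per row
        mask[np.arange(n_regions), rng.integers(0, n_samples, n_regions)] = False
        arr[mask] = np.nan
    return pd.DataFrame(
        arr,
        index=[f"r{i:03d}" for i in range(n_regions)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )
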