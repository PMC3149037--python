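"""Shared fixtures: small synthetic cohorts built per test session."""

import numpy as np
import pandas as pd
import pytest

from arraycnv.simdata import SimConfig, build_marker_map, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """10-sample, 500-marker null cohort (no CNVs, no artifacts)."""
    cfg = SimConfig(markers_per_chrom=500, n_cases=5, n_controls=5, seed=1)
    markers = build_marker_map(cfg)
    panel, samples, truth = simulate_cohort(markers, cfg)
    return cfg, panel, samples, truth


@pytest.fixture(scope="session")
def cnv_cohort():
    """Cohort with random background CNVs for caller/filter tests."""
    cfg = SimConfig(markers_per_chrom=1500, n_cases=15, n_controls=15,
                    seed=3, cnvs_per_sample=1.5)
    markers = build_marker_map(cfg)
    panel, samples, truth = simulate_cohort(markers, cfg)
    return cfg, panel, samples, truth


def make_markers(n=100, chrom="chr1", spacing=10_000, pfb=0.5):
    """Minimal hand-built marker map for unit tests."""
    return pd.DataFrame({
        "marker_id": [f"{chrom}_t{i:04d}" for i in range(n)],
        "chrom": chrom,
        "arm": "q",
        "pos": np.arange(n, dtype=np.int64) * spacing + 1,
        "probe_class": "snp",
        "pfb": pfb,
        "unstable_region": False,
        "gender_linked": False,
    })


def make_samples(n_cases, n_controls, source_split=False):
    rows = []
    for i in range(n_cases):
        rows.append(("case_%03d" % i, "male" if i % 2 else "female",
                     "case", "blood", "T"))
    for i in range(n_controls):
        rows.append(("ctrl_%03d" % i, "male" if i % 2 else "female",
                     "control",
                     "cell_line" if source_split else "blood", "T"))
    return pd.DataFrame(rows, columns=["sample_id", "sex", "phenotype",
                                       "dna_source", "study"])


def make_call(sample_id, chrom, start, end, cn=1, n_markers=5, conf=20.0):
    return {"sample_id": sample_id, "chrom": chrom, "start_pos": start,
            "end_pos": end, "cn": cn, "n_markers": n_markers,
            "length_bp": end - start + 1, "confidence": conf}
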