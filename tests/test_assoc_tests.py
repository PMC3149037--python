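"""Exact carrier tests, scan collapsing, max-T permutation machinery."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from arraycnv.assoc_tests import (
    ContingencyTable,
    carrier_status,
    fisher_one_sided,
    maxT_genomewide,
    odds_ratio,
    replicate_locus,
    scan,
    study_wide_correction,
)
from arraycnv.core import ArrayCnvError, empty_callset
from conftest import make_call, make_markers, make_samples

MARKERS = make_markers(60, spacing=50_000)


def _oracle_p(a, b, c, d):
    """Exhaustive hypergeometric tail sum, independent of scipy."""
    n1, n2 = a + b, c + d
    k = a + c
    total = math.comb(n1 + n2, k)
    if total == 0:
        return 1.0
    s = sum(math.comb(n1, i) * math.comb(n2, k - i)
            for i in range(a, min(n1, k) + 1))
    return s / total


class TestFisher:
    def test_replication_table_printed_values(self):
        t = ContingencyTable(10, 386, 8, 848)
        assert round(odds_ratio(t), 1) == 2.7
        assert round(fisher_one_sided(t), 2) == 0.03

    def test_usp32_table_printed_odds_ratio(self):
        t = ContingencyTable(30, 786, 8, 848)
        assert round(odds_ratio(t), 1) == 4.0

    def test_symmetric_table(self):
        t = ContingencyTable(5, 15, 5, 15)
        assert odds_ratio(t) == 1.0
        assert fisher_one_sided(t) >= 0.5

    def test_sentinels(self):
        assert odds_ratio(ContingencyTable(3, 7, 0, 10)) == math.inf
        assert math.isnan(odds_ratio(ContingencyTable(0, 0, 0, 0)))
        assert fisher_one_sided(ContingencyTable(0, 0, 0, 0)) == 1.0

    def test_exhaustive_oracle_small_margins(self):
        for n1 in range(0, 17):
            for n2 in range(0, 17):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        t = ContingencyTable(a, n1 - a, c, n2 - c)
                        assert abs(fisher_one_sided(t)
                                   - _oracle_p(a, n1 - a, c, n2 - c)) \
                            < 1e-12

    def test_oracle_sampled_larger_margins(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n1, n2 = rng.integers(1, 31, size=2)
            a, c = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            t = ContingencyTable(int(a), int(n1 - a), int(c),
                                 int(n2 - c))
            assert abs(fisher_one_sided(t)
                       - _oracle_p(t.a, t.b, t.c, t.d)) < 1e-12


class TestCarrierStatus:
    def test_empty_callset_margins(self):
        samples = make_samples(4, 6)
        t, dropped = carrier_status(empty_callset(), samples,
                                    ("chr1", 1, 10**6))
        assert (t.a, t.c) == (0, 0)
        assert (t.n_cases, t.n_controls) == (4, 6)
        assert dropped == []

    def test_compound_het_exclusion_flag(self):
        samples = make_samples(2, 2)
        calls = pd.DataFrame([
            make_call("case_000", "chr1", 100, 200),
            make_call("case_000", "chr1", 500, 600),
            make_call("case_001", "chr1", 100, 200)])
        t_on, dropped = carrier_status(calls, samples, ("chr1", 1, 1000),
                                       exclude_compound_hets=True)
        assert dropped == ["case_000"]
        assert (t_on.a, t_on.n_cases) == (1, 1)
        t_off, _ = carrier_status(calls, samples, ("chr1", 1, 1000),
                                  exclude_compound_hets=False)
        assert (t_off.a, t_off.n_cases) == (2, 2)

    def test_unknown_chromosome_rejected(self):
        samples = make_samples(2, 2)
        with pytest.raises(ArrayCnvError, match="unknown chromosome"):
            carrier_status(empty_callset(), samples, ("chrX", 1, 10),
                           known_chroms={"chr1"})


class TestScan:
    def test_shared_deletion_matches_bruteforce_hypergeometric(self):
        samples = make_samples(10, 10)
        start = int(MARKERS["pos"].iloc[20])
        end = int(MARKERS["pos"].iloc[24])
        calls = pd.DataFrame([make_call(f"case_{i:03d}", "chr1",
                                        start, end) for i in range(3)])
        res = scan(calls, samples, MARKERS, mode="position")
        assert len(res) == 1
        expect = math.comb(10, 3) / math.comb(20, 3)
        assert abs(res["p_nominal"].iloc[0] - expect) < 1e-12

    def test_window_zero_halfwidth_equals_position(self):
        rng = np.random.default_rng(3)
        samples = make_samples(8, 8)
        rows = []
        for i, sid in enumerate(samples["sample_id"]):
            if rng.random() < 0.5:
                j = int(rng.integers(0, 50))
                rows.append(make_call(sid, "chr1",
                                      int(MARKERS["pos"].iloc[j]),
                                      int(MARKERS["pos"].iloc[j + 5])))
        calls = pd.DataFrame(rows)
        a = scan(calls, samples, MARKERS, mode="position")
        b = scan(calls, samples, MARKERS, mode="window", half_width=0)
        pd.testing.assert_series_equal(a["p_nominal"], b["p_nominal"])

    def test_empty_callset_scan_empty(self):
        res = scan(empty_callset(), make_samples(3, 3), MARKERS)
        assert res.empty

    def test_collapsing_preserves_distinct_carrier_sets(self):
        samples = make_samples(5, 5)
        calls = pd.DataFrame([
            make_call("case_000", "chr1", int(MARKERS["pos"].iloc[10]),
                      int(MARKERS["pos"].iloc[20])),
            make_call("ctrl_000", "chr1", int(MARKERS["pos"].iloc[15]),
                      int(MARKERS["pos"].iloc[25]))])
        res = scan(calls, samples, MARKERS, mode="position")
        assert len(res) == 3          # case-only, both, control-only


class TestMaxT:
    def test_exhaustive_matches_bruteforce_enumeration(self):
        """n=6 cohort: empirical p equals direct enumeration over all
        C(6,3) label assignments using scipy's Fisher as the oracle."""
        samples = make_samples(3, 3)
        sids = samples["sample_id"].tolist()
        calls = pd.DataFrame([
            make_call(sids[0], "chr1", int(MARKERS["pos"].iloc[5]),
                      int(MARKERS["pos"].iloc[9])),
            make_call(sids[1], "chr1", int(MARKERS["pos"].iloc[5]),
                      int(MARKERS["pos"].iloc[9])),
            make_call(sids[3], "chr1", int(MARKERS["pos"].iloc[30]),
                      int(MARKERS["pos"].iloc[34]))])
        res = maxT_genomewide(calls, samples, MARKERS, mode="position",
                              n_permutations="exhaustive")

        carrier_sets = [{0, 1}, {3}]
        mins = []
        for case_idx in combinations(range(6), 3):
            pmin = 1.0
            for cs in carrier_sets:
                a = len(cs & set(case_idx))
                k = len(cs)
                table = [[a, 3 - a], [k - a, 3 - (k - a)]]
                pmin = min(pmin, fisher_exact(
                    table, alternative="greater")[1])
            mins.append(pmin)
        mins = np.array(mins)
        for _, r in res.iterrows():
            expect = (mins <= r["p_nominal"] + 1e-12).mean()
            assert abs(r["p_genomewide"] - expect) < 1e-12

    def test_trivial_p_one(self):
        samples = make_samples(3, 3)
        calls = pd.DataFrame([make_call("ctrl_000", "chr1",
                                        int(MARKERS["pos"].iloc[5]),
                                        int(MARKERS["pos"].iloc[9]))])
        res = maxT_genomewide(calls, samples, MARKERS,
                              n_permutations=50, seed=1)
        row = res.iloc[0]
        assert row["p_nominal"] == 1.0
        assert row["p_genomewide"] == 1.0

    def test_empirical_floor(self):
        samples = make_samples(10, 10)
        calls = pd.DataFrame([make_call(f"case_{i:03d}", "chr1",
                                        int(MARKERS["pos"].iloc[5]),
                                        int(MARKERS["pos"].iloc[9]))
                              for i in range(10)])
        res = maxT_genomewide(calls, samples, MARKERS,
                              n_permutations=99, seed=2)
        assert (res["p_genomewide"] >= 1 / 100).all()

    def test_seed_determinism(self):
        samples = make_samples(6, 6)
        calls = pd.DataFrame([make_call("case_000", "chr1",
                                        int(MARKERS["pos"].iloc[5]),
                                        int(MARKERS["pos"].iloc[9]))])
        a = maxT_genomewide(calls, samples, MARKERS, n_permutations=200,
                            seed=42)
        b = maxT_genomewide(calls, samples, MARKERS, n_permutations=200,
                            seed=42)
        pd.testing.assert_frame_equal(a, b)


class TestStudyWide:
    def test_threshold_by_approach_count(self):
        df = pd.DataFrame({"p_genomewide": [0.01, 0.0125, 0.02]})
        out4 = study_wide_correction([df] * 4)
        assert out4[0]["study_wide_threshold"].iloc[0] == 0.0125
        assert out4[0]["study_wide_significant"].tolist() == \
            [True, False, False]
        out1 = study_wide_correction([df])
        assert out1[0]["study_wide_threshold"].iloc[0] == 0.05

    def test_zero_approaches_rejected(self):
        with pytest.raises(ArrayCnvError):
            study_wide_correction([])


class TestReplication:
    def test_zero_carriers(self):
        res = replicate_locus(empty_callset(), make_samples(5, 5),
                              ("chr6", 161_688_579, 163_068_824))
        assert res["p_one_sided"] == 1.0
        assert math.isnan(res["odds_ratio"]) or res["odds_ratio"] == 0

    def test_all_cases_carriers(self):
        samples = make_samples(3, 3)
        calls = pd.DataFrame([make_call(f"case_{i:03d}", "chr6",
                                        161_700_000, 161_800_000)
                              for i in range(3)])
        res = replicate_locus(calls, samples,
                              ("chr6", 161_688_579, 163_068_824))
        assert res["odds_ratio"] == math.inf
        assert abs(res["p_one_sided"] - 1 / math.comb(6, 3)) < 1e-12

    def test_compound_hets_removed_from_margins(self):
        samples = make_samples(4, 4)
        calls = pd.DataFrame([
            make_call("case_000", "chr6", 161_700_000, 161_800_000),
            make_call("case_000", "chr6", 162_000_000, 162_100_000),
            make_call("case_001", "chr6", 161_700_000, 161_800_000)])
        res = replicate_locus(calls, samples,
                              ("chr6", 161_688_579, 163_068_824))
        assert res["compound_het_excluded"] == ["case_000"]
        assert res["table"].n_cases == 3

    def test_power_at_replication_effect_size(self):
        """A locus carried at 2.5% in cases vs 0.9% in controls
        (n=400/850) rejects at nominal 0.05 in most replicates."""
        rng = np.random.default_rng(13)
        samples = make_samples(400, 850)
        sids = samples["sample_id"].tolist()
        wins = 0
        reps = 11
        for _ in range(reps):
            rows = []
            for i, sid in enumerate(sids):
                p = 0.025 if i < 400 else 0.009
                if rng.random() < p:
                    rows.append(make_call(sid, "chr6", 161_700_000,
                                          161_800_000))
            res = replicate_locus(pd.DataFrame(rows) if rows
                                  else empty_callset(), samples,
                                  ("chr6", 161_688_579, 163_068_824))
            if res["p_one_sided"] < 0.05:
                wins += 1
        assert wins > reps / 2
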