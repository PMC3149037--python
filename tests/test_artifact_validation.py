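"""LOH/VNTR diagnostics and the molecular-validation calculators."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arraycnv.artifact_validation import (
    gel_size_and_repeats,
    haplotype_frequency_em,
    loh_check,
    mlpa_classify,
    qpcr_classify,
    repeat_decompose,
    summed_allele_test,
    vntr_check,
)
from arraycnv.core import ArrayCnvError
from arraycnv.hmm_caller import HmmParams, call_cnvs
from arraycnv.simdata import SimConfig, build_marker_map, simulate_cohort


def _hap_genotypes(rng, n, k, h, background=0.002):
    """Unphased minor-dosage matrix under the two-haplotype model."""
    nh = rng.binomial(2, h, size=n)
    extra = rng.binomial(np.maximum(2 - nh, 0)[:, None], background,
                         size=(n, k))
    return nh[:, None] + extra, nh


class TestLohCheck:
    def test_artifact_signature_flagged(self):
        rng = np.random.default_rng(5)
        dos, nh = _hap_genotypes(rng, 400, 9, 0.04)
        ids = [f"s{i}" for i in range(400)]
        df = pd.DataFrame(dos, index=ids,
                          columns=[f"snp{j}" for j in range(9)])
        carriers = [ids[i] for i in range(400)
                    if nh[i] == 0 and dos[i].sum() == 0][:20]
        diag = loh_check(df, carriers)
        assert diag.defined and diag.flag
        assert diag.hap_freq_carriers < 0.005
        assert diag.hap_freq_noncarriers > 0.01
        assert diag.het_rate_carriers == 0.0

    def test_null_carrier_split_not_flagged(self):
        flags = 0
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            dos, _ = _hap_genotypes(rng, 400, 9, 0.04)
            ids = [f"s{i}" for i in range(400)]
            df = pd.DataFrame(dos, index=ids,
                              columns=[f"snp{j}" for j in range(9)])
            carriers = list(rng.choice(ids, size=25, replace=False))
            flags += loh_check(df, carriers).flag
        assert flags == 0

    def test_single_carrier_reduces_to_direct_count(self):
        rng = np.random.default_rng(7)
        dos, nh = _hap_genotypes(rng, 300, 9, 0.05)
        ids = [f"s{i}" for i in range(300)]
        df = pd.DataFrame(dos, index=ids,
                          columns=[f"snp{j}" for j in range(9)])
        hom = [ids[i] for i in range(300) if (dos[i] == 0).all()][:1]
        diag = loh_check(df, hom)
        assert diag.hap_freq_carriers == pytest.approx(0.0, abs=1e-6)

    def test_too_few_qualifying_snps_undefined(self):
        rng = np.random.default_rng(9)
        dos = rng.binomial(2, 0.4, size=(100, 9))   # common, unlinked
        df = pd.DataFrame(dos, index=[f"s{i}" for i in range(100)],
                          columns=[f"snp{j}" for j in range(9)])
        diag = loh_check(df, ["s0", "s1"])
        assert not diag.defined and not diag.flag

    def test_em_recovers_frequency(self):
        rng = np.random.default_rng(3)
        for h in (0.02, 0.05, 0.10):
            dos, _ = _hap_genotypes(rng, 3000, 9, h)
            est = haplotype_frequency_em(dos)
            assert abs(est - h) < 0.01


class TestVntrCheck:
    SCENARIO = dict(markers_per_chrom=400, n_cases=100, n_controls=100,
                    vntr_enabled=True, vntr_slope=1.0,
                    vntr_source_shift=-0.45)

    def test_source_confounding_flagged(self):
        cfg = SimConfig(seed=52, **self.SCENARIO)
        m = build_marker_map(cfg)
        panel, samples, truth = simulate_cohort(m, cfg)
        params = HmmParams.from_preset("lenient")
        calls = call_cnvs(panel, params)
        diag = vntr_check(calls, truth.vntr["probe_ids"], samples, panel,
                          caller_params=params,
                          repeat_counts=truth.vntr["summed_repeats"])
        assert diag.flag
        assert diag.source_assoc_p < 0.01
        assert diag.recall_delta == 1.0
        assert diag.lrr_vs_repeat_slope > 0
        assert diag.lrr_vs_repeat_p < 1e-6
        # spurious phenotype imbalance: carriers concentrate in one group
        a, b, c, d = diag.source_table
        assert (a == 0) or (c == 0) or abs(a - c) > 20

    def test_null_shift_silent(self):
        flags = 0
        for seed in (41, 42, 43):
            cfg = SimConfig(markers_per_chrom=400, n_cases=60,
                            n_controls=60, seed=seed, vntr_enabled=True,
                            vntr_slope=0.0, vntr_source_shift=0.0)
            m = build_marker_map(cfg)
            panel, samples, truth = simulate_cohort(m, cfg)
            params = HmmParams.from_preset("lenient")
            calls = call_cnvs(panel, params)
            diag = vntr_check(calls, truth.vntr["probe_ids"], samples,
                              panel, caller_params=params)
            flags += diag.flag
        assert flags == 0

    def test_single_source_cohort_partial_result(self):
        cfg = SimConfig(markers_per_chrom=300, n_cases=20, n_controls=20,
                        seed=44, confound_dna_source=False,
                        vntr_enabled=True, vntr_slope=1.0)
        m = build_marker_map(cfg)
        panel, samples, truth = simulate_cohort(m, cfg)
        diag = vntr_check(call_cnvs(panel), truth.vntr["probe_ids"],
                          samples, panel)
        assert math.isnan(diag.source_assoc_p)
        assert not diag.flag


class TestDosageCalculators:
    @pytest.mark.parametrize("ratio,verdict", [
        (0.74, "deletion"), (1.57, "duplication"), (1.00, "normal"),
        (0.80, "normal"), (1.20, "normal"), (0.799, "deletion")])
    def test_qpcr_thresholds(self, ratio, verdict):
        assert qpcr_classify(ratio, [1.0, 1.0]).verdict == verdict

    def test_qpcr_replicates_averaged_before_classification(self):
        call = qpcr_classify([0.70, 0.78], [1.0, 1.0])
        assert call.ratio == pytest.approx(0.74)
        assert call.verdict == "deletion"

    def test_qpcr_rejects_bad_input(self):
        with pytest.raises(ArrayCnvError):
            qpcr_classify(-1.0, [1.0])
        with pytest.raises(ArrayCnvError):
            qpcr_classify(1.0, [])

    @pytest.mark.parametrize("ratio,verdict", [
        (1.0, "normal"), (0.5, "deletion"), (0.8, "normal"),
        (1.2, "normal"), (1.201, "duplication"), (0.799, "deletion")])
    def test_mlpa_thresholds(self, ratio, verdict):
        assert mlpa_classify(ratio).verdict == verdict

    @given(st.floats(min_value=0.01, max_value=3.0,
                     allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_classifiers_are_pure_threshold_functions(self, r):
        m = mlpa_classify(r)
        order = {"deletion": 0, "normal": 1, "duplication": 2}
        assert m.verdict in order
        if r < 0.8:
            assert m.verdict == "deletion"
        elif r <= 1.2:
            assert m.verdict == "normal"
        else:
            assert m.verdict == "duplication"
        q = qpcr_classify(r, [1.0])
        if 0.80 <= r <= 1.20:
            assert q.verdict == "normal"
        # qPCR bounds are exclusive, MLPA inclusive: they may disagree
        # only exactly at the bounds
        if abs(r - 0.8) > 1e-9 and abs(r - 1.2) > 1e-9:
            assert q.verdict == m.verdict


class TestGelAndRepeats:
    LADDER = [(10.0, 800.0), (30.0, 900.0), (50.0, 1000.0)]

    def test_band_on_ladder_entry(self):
        res = gel_size_and_repeats(30.0, self.LADDER, flank_bp=4.0)
        assert res["size_bp"] == 900.0
        assert res["n_repeats_rounded"] == 28

    def test_linear_interpolation_between_nearest_bands(self):
        res = gel_size_and_repeats(40.0, self.LADDER, flank_bp=0.0)
        assert res["size_bp"] == pytest.approx(950.0)

    def test_size_equal_flank_zero_repeats(self):
        res = gel_size_and_repeats(30.0, self.LADDER, flank_bp=900.0)
        assert res["n_repeats"] == 0.0

    def test_band_outside_ladder_rejected(self):
        with pytest.raises(ArrayCnvError, match="ladder"):
            gel_size_and_repeats(99.0, self.LADDER, flank_bp=0.0)

    def test_reference_allele_arithmetic(self):
        # 13 + 2 + 13 units of a 32-bp repeat plus 4 bp flank = 900 bp
        assert (900 - 4) / 32 == 28
        assert 13 + 2 + 13 == 28


class TestRepeatDecompose:
    A = "ACGTACGTACGTACGTACGTACGTACGTACGT"

    def _variant(self, *subs):
        s = list(self.A)
        for pos, base in subs:
            s[pos] = base
        return "".join(s)

    def test_uniform_repeat(self):
        res = repeat_decompose("ACGT" * 5, unit_len=4)
        assert res["variants"] == {"ACGT": 5}
        assert res["partial_unit"] == ""

    def test_reference_structure_three_forms(self):
        b = self._variant((5, "T"), (15, "G"))
        c = self._variant((5, "G"))
        seq = self.A * 13 + b * 2 + c * 13
        res = repeat_decompose(seq, unit_len=32)
        assert sorted(res["variants"].values()) == [2, 13, 13]
        assert len(res["variants"]) == 3
        assert len(res["diff_positions"]) == 2
        assert res["runs"] == [(self.A, 13), (b, 2), (c, 13)]

    def test_trailing_partial_reported_not_counted(self):
        res = repeat_decompose("ACGT" * 3 + "AC", unit_len=4)
        assert res["n_units"] == 3
        assert res["partial_unit"] == "AC"

    def test_too_short_rejected(self):
        with pytest.raises(ArrayCnvError):
            repeat_decompose("ACG", unit_len=4)

    @given(st.lists(st.tuples(st.sampled_from("ABC"),
                              st.integers(1, 6)),
                    min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_decompose_inverts_construction(self, runs):
        unit = {"A": "AAAT", "B": "AACT", "C": "AAGT"}
        seq = "".join(unit[v] * n for v, n in runs)
        res = repeat_decompose(seq, unit_len=4)
        counts = {}
        for v, n in runs:
            counts[unit[v]] = counts.get(unit[v], 0) + n
        assert res["variants"] == counts
        assert res["n_units"] == sum(n for _, n in runs)


class TestSummedAlleleTest:
    def test_identical_groups_p_one(self):
        t, p = summed_allele_test([10, 10, 10], [10, 10, 10])
        assert p == 1.0

    def test_separated_groups_significant_and_matches_closed_form(self):
        t, p = summed_allele_test([10, 10, 10], [20, 20, 20])
        assert p < 0.01
        a = np.array([54.0, 56.0, 58.0, 55.0])
        b = np.array([57.0, 59.0, 61.0, 60.0])
        t2, p2 = summed_allele_test(list(a), list(b))
        sp = math.sqrt(((len(a) - 1) * a.var(ddof=1)
                        + (len(b) - 1) * b.var(ddof=1))
                       / (len(a) + len(b) - 2))
        t_manual = (a.mean() - b.mean()) / (
            sp * math.sqrt(1 / len(a) + 1 / len(b)))
        assert t2 == pytest.approx(t_manual)

    def test_null_split_not_significant(self):
        rng = np.random.default_rng(17)
        sizes = 56 + rng.integers(-6, 7, size=40)
        split = rng.permutation(40)
        t, p = summed_allele_test(list(sizes[split[:20]]),
                                  list(sizes[split[20:]]))
        assert p > 0.05

    def test_small_groups_rejected(self):
        with pytest.raises(ArrayCnvError):
            summed_allele_test([1.0], [2.0, 3.0])
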