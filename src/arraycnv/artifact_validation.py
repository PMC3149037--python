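"""Artifact diagnostics and molecular-validation calculators.

Two artifact mechanisms can produce spurious, highly significant CNV
associations on SNP arrays:

* **Low-MAF LOH blocks** — a run of SNPs whose minor alleles ride one
  rare haplotype leaves most samples homozygous across the run (BAF
  only near 0/1), which a BAF-aware caller can interpret as a deletion.
  :func:`loh_check` estimates the all-minor-haplotype frequency in
  deletion-call carriers versus the rest by a two-class EM on unphased
  genotypes; the artifact signature is a carrier haplotype frequency of
  ~0 with zero carrier heterozygosity while the background frequency is
  clearly positive.

* **VNTR probes confounded with DNA source** — monomorphic probes
  tagging a variable-number tandem repeat track repeat length, not
  deletion/duplication, and carry batch shifts between blood and
  cell-line DNA.  :func:`vntr_check` tests call status against DNA
  source, re-calls the chromosome with the probe group masked, and
  regresses probe LRR on true repeat count when truth is available.

The calculators mirror standard wet-lab dosage rules: qPCR proportions
below 0.80 suggest deletion and above 1.20 duplication (exclusive
bounds); MLPA peak ratios in [0.8, 1.2] are normal (inclusive bounds);
gel bands are sized by linear interpolation between the two nearest
ladder bands and converted to repeat units as (size - flank)/unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ArrayCnvError, IntensityPanel

__all__ = [
    "LohDiagnostic",
    "VntrDiagnostic",
    "ValidationCall",
    "loh_check",
    "vntr_check",
    "qpcr_classify",
    "mlpa_classify",
    "gel_size_and_repeats",
    "repeat_decompose",
    "summed_allele_test",
    "haplotype_frequency_em",
]


# ------------------------------------------------------------------- LOH

@dataclass
class LohDiagnostic:
    region: tuple[str, int, int] | None
    snp_ids: list[str]
    hap_freq_carriers: float
    hap_freq_noncarriers: float
    het_rate_carriers: float
    het_rate_noncarriers: float
    flag: bool
    defined: bool = True


def composite_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared genotype (composite) correlation between two SNP dosage
    vectors; phase-free stand-in for haplotype r^2."""
    ok = np.isfinite(g1) & np.isfinite(g2)
    if ok.sum() < 3 or np.std(g1[ok]) == 0 or np.std(g2[ok]) == 0:
        return 0.0
    r = np.corrcoef(g1[ok], g2[ok])[0, 1]
    return float(r * r)


def haplotype_frequency_em(dosages: np.ndarray, max_iter: int = 200,
                           tol: float = 1e-8) -> float:
    """Frequency of the all-minor-allele haplotype by a two-class EM.

    ``dosages``: (n_samples, n_snps) minor-allele counts in {0,1,2}.
    The region is treated as biallelic: each chromosome carries either
    the all-minor haplotype H (frequency h) or some other haplotype O;
    residual minor alleles on O occur independently per SNP with a
    frequency estimated in the M-step.  Returns h.
    """
    d = np.asarray(dosages, dtype=float)
    n, k = d.shape
    if n == 0:
        return float("nan")
    h = max(d.min(axis=1).mean() / 2.0, 1e-4)
    eps = np.clip(d.mean(axis=0) / 2.0, 1e-6, 0.2)
    for _ in range(max_iter):
        # P(dosage_j | n_H) with background minor alleles Binom(2-nH, eps_j)
        logp = np.full((n, 3), -np.inf)
        for nh in range(3):
            extra = d - nh
            valid = np.all((extra >= 0) & (extra <= 2 - nh), axis=1)
            with np.errstate(divide="ignore"):
                ll = np.where(
                    valid[:, None],
                    stats.binom.logpmf(np.clip(extra, 0, 2), 2 - nh, eps),
                    -np.inf)
            prior = stats.binom.logpmf(nh, 2, h)
            logp[:, nh] = np.where(valid, ll.sum(axis=1) + prior, -np.inf)
        mx = logp.max(axis=1, keepdims=True)
        w = np.exp(logp - mx)
        w /= w.sum(axis=1, keepdims=True)
        h_new = float((w @ np.arange(3)).sum() / (2 * n))
        e_nh = w @ np.arange(3)
        denom = np.maximum(2 - e_nh, 1e-9)
        eps_new = np.clip(
            ((d - e_nh[:, None]).clip(min=0)).sum(axis=0)
            / denom.sum(), 1e-6, 0.5)
        if abs(h_new - h) < tol:
            h = h_new
            break
        h, eps = h_new, eps_new
    return float(np.clip(h, 0.0, 1.0))


def select_loh_panel(dosages: pd.DataFrame, maf_cut: float = 0.05,
                     r2_cut: float = 0.75) -> list[str]:
    """SNPs with MAF below the cut whose pairwise composite r^2 exceeds
    the cut (largest connected group under the r^2 relation)."""
    maf = dosages.mean(axis=0) / 2.0
    maf = np.minimum(maf, 1 - maf)
    cand = [c for c in dosages.columns if 0 < maf[c] < maf_cut]
    if len(cand) < 2:
        return cand
    adj = {c: set() for c in cand}
    for i, ci in enumerate(cand):
        for cj in cand[i + 1:]:
            if composite_r2(dosages[ci].to_numpy(),
                            dosages[cj].to_numpy()) > r2_cut:
                adj[ci].add(cj)
                adj[cj].add(ci)
    best: list[str] = []
    seen: set[str] = set()
    for start in cand:
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(adj[u] - seen)
        if len(comp) > len(best):
            best = comp
    return [c for c in dosages.columns if c in set(best)]


def loh_check(dosages: pd.DataFrame, carrier_ids: list[str],
              region: tuple[str, int, int] | None = None,
              maf_cut: float = 0.05, r2_cut: float = 0.75,
              min_snps: int = 3, background_floor: float = 0.01,
              carrier_eps: float = 0.005) -> LohDiagnostic:
    """Diagnose a deletion-called region for the rare-haplotype artifact.

    ``dosages``: samples x SNPs minor-allele counts for the region;
    ``carrier_ids``: samples assigned a deletion call there.  The
    qualifying SNP panel (low MAF, tight LD) is selected first; with
    fewer than ``min_snps`` qualifying SNPs the diagnostic is undefined
    and not flagged.  The artifact is flagged when the carrier
    haplotype frequency is ~0, carriers show zero heterozygosity over
    the panel, and the non-carrier frequency exceeds the floor.
    """
    panel = select_loh_panel(dosages, maf_cut, r2_cut)
    if len(panel) < min_snps:
        return LohDiagnostic(region=region, snp_ids=panel,
                             hap_freq_carriers=float("nan"),
                             hap_freq_noncarriers=float("nan"),
                             het_rate_carriers=float("nan"),
                             het_rate_noncarriers=float("nan"),
                             flag=False, defined=False)
    sub = dosages[panel]
    in_carrier = sub.index.isin(set(carrier_ids))
    carr = sub.loc[in_carrier].to_numpy()
    rest = sub.loc[~in_carrier].to_numpy()
    h_carr = haplotype_frequency_em(carr) if len(carr) else float("nan")
    h_rest = haplotype_frequency_em(rest) if len(rest) else float("nan")
    het_carr = float((carr == 1).mean()) if len(carr) else float("nan")
    het_rest = float((rest == 1).mean()) if len(rest) else float("nan")
    flag = (len(carr) > 0 and not math.isnan(h_carr)
            and h_carr < carrier_eps and het_carr == 0.0
            and not math.isnan(h_rest) and h_rest > background_floor)
    return LohDiagnostic(region=region, snp_ids=panel,
                         hap_freq_carriers=h_carr,
                         hap_freq_noncarriers=h_rest,
                         het_rate_carriers=het_carr,
                         het_rate_noncarriers=het_rest,
                         flag=bool(flag))


# ------------------------------------------------------------------ VNTR

@dataclass
class VntrDiagnostic:
    probe_ids: list[str]
    source_assoc_p: float
    source_table: tuple[int, int, int, int] | None
    recall_delta: float
    lrr_vs_repeat_slope: float = float("nan")
    lrr_vs_repeat_p: float = float("nan")
    flag: bool = False


def vntr_check(calls: pd.DataFrame, probe_ids: list[str],
               samples: pd.DataFrame, panel: IntensityPanel,
               caller_params=None,
               repeat_counts: pd.Series | None = None,
               source_alpha: float = 0.05) -> VntrDiagnostic:
    """Diagnose a probe group for VNTR / DNA-source confounding.

    Components: (i) two-sided Fisher exact test of call-carrier status
    at the probe group against DNA source; (ii) re-calling the
    chromosome with the probes masked and reporting the fraction of
    region calls lost; (iii) when true summed repeat counts are known,
    the regression of the per-sample mean probe LRR on repeat count.
    With a single-source cohort the source test is undefined (p NaN)
    but the other components still run.
    """
    from .hmm_caller import HmmParams, call_cnvs

    markers = panel.markers
    in_group = markers["marker_id"].isin(set(probe_ids)).to_numpy()
    if not in_group.any():
        raise ArrayCnvError("probe group matches no marker")
    gpos = markers.loc[in_group, "pos"]
    chrom = str(markers.loc[in_group, "chrom"].iloc[0])
    g0, g1 = int(gpos.min()), int(gpos.max())

    region = calls[(calls["chrom"] == chrom)
                   & (calls["start_pos"] <= g1)
                   & (calls["end_pos"] >= g0)]
    carriers = set(region["sample_id"])
    is_carrier = samples["sample_id"].isin(carriers).to_numpy()
    cell = (samples["dna_source"] == "cell_line").to_numpy()
    if cell.all() or (~cell).all():
        p_src, table = float("nan"), None
    else:
        a = int((is_carrier & ~cell).sum())   # blood carriers
        b = int((~is_carrier & ~cell).sum())
        c = int((is_carrier & cell).sum())
        d = int((~is_carrier & cell).sum())
        table = (a, b, c, d)
        _, p_src = stats.fisher_exact([[a, b], [c, d]])
        p_src = float(p_src)

    params = caller_params or HmmParams()
    before = len(region)
    if before:
        mask = ~in_group
        on_chrom = (markers["chrom"] == chrom).to_numpy()
        recalls = call_cnvs(panel, params,
                            marker_mask=mask | ~on_chrom)
        after = len(recalls[(recalls["chrom"] == chrom)
                            & (recalls["start_pos"] <= g1)
                            & (recalls["end_pos"] >= g0)])
        recall_delta = 1.0 - after / before
    else:
        recall_delta = 0.0

    slope = p_lin = float("nan")
    if repeat_counts is not None:
        mean_lrr = pd.Series(
            np.nanmean(panel.lrr[:, in_group], axis=1),
            index=panel.samples)
        common = [s for s in panel.samples if s in repeat_counts.index]
        if len(common) >= 3:
            fit = stats.linregress(repeat_counts[common].to_numpy(float),
                                   mean_lrr[common].to_numpy(float))
            slope, p_lin = float(fit.slope), float(fit.pvalue)

    flag = bool((not math.isnan(p_src) and p_src < source_alpha)
                and recall_delta >= 0.5)
    return VntrDiagnostic(probe_ids=list(probe_ids),
                          source_assoc_p=p_src, source_table=table,
                          recall_delta=float(np.clip(recall_delta, 0, 1)),
                          lrr_vs_repeat_slope=slope,
                          lrr_vs_repeat_p=p_lin, flag=flag)


# ------------------------------------------------- dosage ratio calculators

@dataclass(frozen=True)
class ValidationCall:
    assay: str
    ratio: float
    verdict: str   # deletion / normal / duplication


def qpcr_classify(sample_quantities: float | list[float],
                  control_quantities: list[float]) -> ValidationCall:
    """Classify a qPCR dosage proportion against the control mean.

    Each replicate proportion is quantity / mean(controls); replicate
    proportions are averaged before applying the exclusive 0.80/1.20
    thresholds.
    """
    controls = np.asarray(control_quantities, dtype=float)
    if controls.size == 0 or controls.mean() <= 0:
        raise ArrayCnvError("control mean must be positive")
    q = np.atleast_1d(np.asarray(sample_quantities, dtype=float))
    if (q <= 0).any():
        raise ArrayCnvError("non-positive sample quantity")
    ratio = float((q / controls.mean()).mean())
    if ratio < 0.80:
        verdict = "deletion"
    elif ratio > 1.20:
        verdict = "duplication"
    else:
        verdict = "normal"
    return ValidationCall(assay="qpcr", ratio=ratio, verdict=verdict)


def mlpa_classify(peak_ratio: float) -> ValidationCall:
    """Classify an MLPA peak ratio; [0.8, 1.2] inclusive is normal."""
    if peak_ratio <= 0:
        raise ArrayCnvError("peak ratio must be positive")
    if peak_ratio < 0.8:
        verdict = "deletion"
    elif peak_ratio > 1.2:
        verdict = "duplication"
    else:
        verdict = "normal"
    return ValidationCall(assay="mlpa", ratio=float(peak_ratio),
                          verdict=verdict)


# ------------------------------------------------------- gel and repeats

def gel_size_and_repeats(band_pixel: float,
                         ladder_pixels_bp: list[tuple[float, float]],
                         flank_bp: float,
                         unit_len: int = 32) -> dict:
    """Size a gel band between its two nearest ladder bands and convert
    to repeat units.

    ``ladder_pixels_bp``: (pixel, bp) reference bands.  Size is linear
    interpolation between the flanking ladder bands; repeats =
    (size - flank_bp) / unit_len, reported unrounded and rounded.
    """
    ladder = sorted(ladder_pixels_bp)
    px = [p for p, _ in ladder]
    if not (px[0] <= band_pixel <= px[-1]):
        raise ArrayCnvError("band outside ladder range")
    hi = next(i for i, p in enumerate(px) if p >= band_pixel)
    if px[hi] == band_pixel:
        size = ladder[hi][1]
    else:
        (p0, b0), (p1, b1) = ladder[hi - 1], ladder[hi]
        size = b0 + (band_pixel - p0) / (p1 - p0) * (b1 - b0)
    repeats = (size - flank_bp) / unit_len
    return {"size_bp": float(size), "n_repeats": float(repeats),
            "n_repeats_rounded": int(round(repeats))}


def repeat_decompose(sequence: str, unit_len: int = 32,
                     anchor: int = 0) -> dict:
    """Tile a sequence into consecutive repeat units and cluster them.

    Greedy tiling into ``unit_len`` blocks from ``anchor``; blocks are
    grouped by exact sequence.  Returns the ordered run-length
    decomposition, distinct variants with counts, the positions at
    which variants differ, and any trailing partial unit (reported but
    not counted).
    """
    seq = sequence[anchor:]
    if len(seq) < unit_len:
        raise ArrayCnvError("sequence shorter than one repeat unit")
    n_full = len(seq) // unit_len
    units = [seq[i * unit_len:(i + 1) * unit_len] for i in range(n_full)]
    partial = seq[n_full * unit_len:]
    runs: list[tuple[str, int]] = []
    for u in units:
        if runs and runs[-1][0] == u:
            runs[-1] = (u, runs[-1][1] + 1)
        else:
            runs.append((u, 1))
    variants: dict[str, int] = {}
    for u in units:
        variants[u] = variants.get(u, 0) + 1
    var_seqs = list(variants)
    diff_positions = [i for i in range(unit_len)
                      if len({v[i] for v in var_seqs}) > 1]
    return {"runs": runs, "variants": variants,
            "n_units": n_full, "diff_positions": diff_positions,
            "partial_unit": partial}


def summed_allele_test(group_a_sizes: list[float],
                       group_b_sizes: list[float]) -> tuple[float, float]:
    """Equal-variance two-sample Student t-test on summed allele sizes.

    Returns (t, two-sided p); identical degenerate groups give p = 1.
    """
    a = np.asarray(group_a_sizes, dtype=float)
    b = np.asarray(group_b_sizes, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ArrayCnvError("each group needs at least two measurements")
    if np.std(a) == 0 and np.std(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
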