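"""Synthetic SNP-array cohorts with known CNV/mosaic/artifact ground truth.

The generator emulates the statistical structure of Illumina-style
LRR/BAF intensity data for a case-control cohort:

* diploid SNP markers with Hardy-Weinberg genotypes at marker-specific
  B-allele frequencies, BAF clustered at {0, 1/2, 1} and LRR centred at 0;
* implanted germline CNVs (copy numbers 0, 1, 3, 4) shifting LRR to
  state-specific means and BAF to b/c genotype fractions;
* whole-arm mosaicism at cell fraction f, which splits the heterozygote
  BAF band to (1-f)/(2-f) and 1/(2-f) for a loss, 1/(2+f) and (1+f)/(2+f)
  for a gain, with an LRR shift of f times the full-event mean;
* three classes of sex-cross-hybridizing markers (patterns B/C/D);
* a monomorphic VNTR probe group whose LRR tracks summed repeat length
  and carries a DNA-source batch shift;
* a low-MAF tight-LD SNP block whose minor alleles ride a single rare
  haplotype, producing long homozygous (LOH-like) BAF runs in
  non-carriers.

Randomness is organised so that each sample owns an independent stream
split from the master seed: adding samples never perturbs the signal of
existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    IntensityPanel,
    LRR_MEANS,
    PFB_MONOMORPHIC,
    validate_marker_map,
)

__all__ = [
    "SimConfig",
    "TruthSet",
    "build_marker_map",
    "simulate_cohort",
    "inject_artifacts",
]

# Stream labels: master seed is combined with one of these to derive
# independent generators (np.random accepts integer-sequence seeds).
_STREAM_MAP = 0
_STREAM_COHORT = 2
_STREAM_ARTIFACT_PICK = 4
_STREAM_ARTIFACT_SAMPLE = 5


@dataclass
class SimConfig:
    """Full description of a synthetic cohort; the seed fixes every bit.

    Counts and noise levels default to a small panel suitable for tests;
    scale ``chrom_lengths``/``markers_per_chrom``/sample counts up for
    power studies.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000})
    markers_per_chrom: int | dict[str, int] = 2000
    centromere_frac: float = 0.4
    cnv_probe_frac: float = 0.06
    unstable_margin: int = 2          # markers flagged unstable at each arm end
    pfb_range: tuple[float, float] = (0.05, 0.95)

    n_cases: int = 50
    n_controls: int = 50
    confound_dna_source: bool = True  # cases blood / controls cell line
    lrr_sd: float = 0.2
    lrr_sd_cell_line: float | None = None
    baf_sd: float = 0.03
    lrr_means: tuple[float, ...] = LRR_MEANS
    intensity_scale: float = 1.5      # R at two copies when emitting raw X/Y
    emit_xy: bool = False

    # germline CNVs
    cnvs_per_sample: float = 0.0      # Poisson mean for random background CNVs
    cnv_marker_range: tuple[int, int] = (10, 60)
    cnv_cn_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.45, 3: 0.40, 4: 0.10})
    cnv_specs: list[dict[str, Any]] = field(default_factory=list)
    # shared locus carried at different case/control frequencies
    locus_carrier: dict[str, Any] | None = None

    # mosaic arms: each entry {sample, chrom, arm, direction, fraction}
    mosaic_arms: list[dict[str, Any]] = field(default_factory=list)

    # artifacts
    gender_linked: dict[str, int] = field(default_factory=dict)  # pattern -> n
    vntr_enabled: bool = False
    vntr_n_probes: int = 6
    vntr_ref_repeats: int = 28        # repeats per reference allele
    vntr_repeat_spread: int = 6       # allele repeats uniform in ref +/- spread
    vntr_slope: float = 1.0
    vntr_source_shift: float = 0.0    # LRR shift added for cell-line DNA
    loh_enabled: bool = False
    loh_n_snps: int = 9
    loh_hap_freq: float = 0.041
    # residual minor alleles off the rare haplotype; kept small so the
    # block's pairwise composite r^2 stays clearly above 0.75 (the
    # tight-LD structure the block emulates) while LD stays imperfect
    loh_background_minor: float = 0.002
    loh_lrr_bias: float = -0.3
    loh_reported_pfb: float = 0.5     # PFB written to the map for the block

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError("sample counts must be >= 0")
        for c, ln in self.chrom_lengths.items():
            if ln <= 0:
                raise ConfigError(f"non-positive length for {c}")
            if self.markers_for(c) <= 0:
                raise ConfigError(f"zero markers declared on {c}")
        if self.lrr_sd <= 0 or self.baf_sd <= 0:
            raise ConfigError("noise sds must be positive")
        if not 0 < self.centromere_frac < 1:
            raise ConfigError("centromere_frac must be in (0,1)")
        for entry in self.mosaic_arms:
            f = entry.get("fraction")
            if f is None or not 0 < f <= 1:
                raise ConfigError("mosaic fraction must be in (0,1]")

    def markers_for(self, chrom: str) -> int:
        if isinstance(self.markers_per_chrom, dict):
            return int(self.markers_per_chrom[chrom])
        return int(self.markers_per_chrom)


@dataclass
class TruthSet:
    """Ground-truth annotations emitted alongside a simulated panel."""

    germline_cnvs: pd.DataFrame
    mosaic_arms: pd.DataFrame
    gender_linked_markers: pd.DataFrame
    vntr: dict[str, Any] | None = None
    loh: dict[str, Any] | None = None

    @staticmethod
    def empty() -> "TruthSet":
        return TruthSet(
            germline_cnvs=pd.DataFrame(
                columns=["sample_id", "chrom", "start_pos", "end_pos", "cn"]),
            mosaic_arms=pd.DataFrame(
                columns=["sample_id", "chrom", "arm", "direction", "fraction"]),
            gender_linked_markers=pd.DataFrame(columns=["marker_id", "pattern"]),
        )


def build_marker_map(config: SimConfig) -> pd.DataFrame:
    """Build an ordered synthetic array manifest.

    Positions are strictly increasing per chromosome; each chromosome is
    split into p/q arms at ``centromere_frac`` of its length; a configured
    fraction of markers are monomorphic copy-number probes carrying the
    PFB sentinel; the first/last ``unstable_margin`` markers of every arm
    are flagged as unstable regions.
    """
    rng = np.random.default_rng([config.seed, _STREAM_MAP])
    frames = []
    for chrom in config.chrom_lengths:
        length = config.chrom_lengths[chrom]
        n = config.markers_for(chrom)
        if n > length // 2:
            raise ConfigError(f"too many markers for length of {chrom}")
        # sorted draws plus an offset ramp guarantee strict increase
        pos = np.sort(rng.integers(1, length - n, size=n)) + np.arange(n)
        cen = int(length * config.centromere_frac)
        arm = np.where(pos <= cen, "p", "q")
        is_cnv = rng.random(n) < config.cnv_probe_frac
        pfb = rng.uniform(*config.pfb_range, size=n)
        pfb[is_cnv] = PFB_MONOMORPHIC
        unstable = np.zeros(n, dtype=bool)
        for a in ("p", "q"):
            idx = np.flatnonzero(arm == a)
            if len(idx):
                m = min(config.unstable_margin, len(idx))
                unstable[idx[:m]] = True
                unstable[idx[-m:]] = True
        frames.append(pd.DataFrame({
            "marker_id": [f"{chrom}_m{i:06d}" for i in range(n)],
            "chrom": chrom,
            "arm": arm,
            "pos": pos.astype(np.int64),
            "probe_class": np.where(is_cnv, "cnv_probe", "snp"),
            "pfb": pfb,
            "unstable_region": unstable,
            "gender_linked": False,
        }))
    return validate_marker_map(pd.concat(frames, ignore_index=True))


def _build_samples(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_cases):
        rows.append({
            "sample_id": f"case_{i:04d}",
            "sex": "male" if i % 2 == 0 else "female",
            "phenotype": "case",
            "dna_source": "blood",
            "study": "SIM",
        })
    for i in range(config.n_controls):
        rows.append({
            "sample_id": f"ctrl_{i:04d}",
            "sex": "male" if i % 2 == 0 else "female",
            "phenotype": "control",
            "dna_source": "cell_line" if config.confound_dna_source else "blood",
            "study": "SIM",
        })
    return pd.DataFrame(rows, columns=[
        "sample_id", "sex", "phenotype", "dna_source", "study"])


def _marker_span(markers: pd.DataFrame, chrom: str,
                 start_pos: int, end_pos: int) -> np.ndarray:
    sel = ((markers["chrom"] == chrom)
           & (markers["pos"] >= start_pos) & (markers["pos"] <= end_pos))
    return np.flatnonzero(sel.to_numpy())


def _draw_cnv_intervals(markers: pd.DataFrame, config: SimConfig,
                        samples: pd.DataFrame) -> pd.DataFrame:
    """Resolve explicit specs, the shared carrier locus and random
    background CNVs into one truth table of (sample, interval, cn)."""
    pos = markers["pos"].to_numpy()
    chrom_arr = markers["chrom"].to_numpy()
    chrom_idx = {c: np.flatnonzero(chrom_arr == c)
                 for c in pd.unique(chrom_arr)}
    sample_ids = samples["sample_id"].tolist()
    phen = samples["phenotype"].to_numpy()
    records: list[dict[str, Any]] = []
    by_sample: dict[str, list[tuple[str, int, int]]] = {s: [] for s in sample_ids}

    def add(sample: str, chrom: str, i0: int, i1: int, cn: int,
            reject_overlap: bool = True) -> bool:
        s0, e0 = int(pos[i0]), int(pos[i1])
        for (c2, a, b) in by_sample[sample]:
            if c2 == chrom and s0 <= b and e0 >= a:
                if reject_overlap:
                    raise ConfigError(
                        f"overlapping truth CNVs for {sample} on {chrom}")
                return False
        by_sample[sample].append((chrom, s0, e0))
        records.append({"sample_id": sample, "chrom": chrom,
                        "start_pos": s0, "end_pos": e0, "cn": int(cn)})
        return True

    for spec in config.cnv_specs:
        sample = spec["sample"]
        if isinstance(sample, int):
            sample = sample_ids[sample]
        chrom = spec["chrom"]
        if "start_marker" in spec:
            i0 = int(spec["start_marker"])
            i1 = i0 + int(spec["n_markers"]) - 1
            idx = chrom_idx[chrom]
            if i1 >= len(idx):
                raise ConfigError("cnv spec extends past chromosome")
            i0, i1 = idx[i0], idx[i1]
        else:
            span = _marker_span(markers, chrom,
                                int(spec["start_pos"]), int(spec["end_pos"]))
            if len(span) == 0:
                raise ConfigError("cnv spec interval covers no marker")
            i0, i1 = span[0], span[-1]
        add(sample, chrom, i0, i1, spec["cn"])

    lc = config.locus_carrier
    if lc is not None:
        span = _marker_span(markers, lc["chrom"],
                            int(lc["start_pos"]), int(lc["end_pos"]))
        if len(span) == 0:
            raise ConfigError("carrier locus covers no marker")
        for si, sample in enumerate(sample_ids):
            rng = np.random.default_rng([config.seed, _STREAM_COHORT, si, 1])
            p = lc["p_case"] if phen[si] == "case" else lc["p_control"]
            if rng.random() < p:
                add(sample, lc["chrom"], span[0], span[-1], int(lc["cn"]))

    if config.cnvs_per_sample > 0:
        chroms = list(chrom_idx)
        weights = np.array([len(chrom_idx[c]) for c in chroms], dtype=float)
        weights /= weights.sum()
        cns = sorted(config.cnv_cn_probs)
        cnp = np.array([config.cnv_cn_probs[c] for c in cns], dtype=float)
        cnp /= cnp.sum()
        for si, sample in enumerate(sample_ids):
            rng = np.random.default_rng([config.seed, _STREAM_COHORT, si, 2])
            for _ in range(rng.poisson(config.cnvs_per_sample)):
                for _attempt in range(50):
                    chrom = chroms[rng.choice(len(chroms), p=weights)]
                    idx = chrom_idx[chrom]
                    nm = int(rng.integers(config.cnv_marker_range[0],
                                          config.cnv_marker_range[1] + 1))
                    if nm > len(idx):
                        continue
                    j0 = int(rng.integers(0, len(idx) - nm + 1))
                    cn = int(cns[rng.choice(len(cns), p=cnp)])
                    if add(sample, chrom, idx[j0], idx[j0 + nm - 1], cn,
                           reject_overlap=False):
                        break
    return pd.DataFrame(records, columns=[
        "sample_id", "chrom", "start_pos", "end_pos", "cn"])


def _loss_bands(f: float) -> tuple[float, float]:
    return (1 - f) / (2 - f), 1 / (2 - f)


def _gain_bands(f: float) -> tuple[float, float]:
    return 1 / (2 + f), (1 + f) / (2 + f)


def simulate_cohort(
    markers: pd.DataFrame, config: SimConfig,
) -> tuple[IntensityPanel, pd.DataFrame, TruthSet]:
    """Generate an intensity panel, sample table and truth set.

    Emits, per sample: HWE genotypes at each SNP's PFB with BAF clusters
    of width ``baf_sd``; LRR noise of width ``lrr_sd`` (optionally
    inflated for cell-line DNA); implanted germline CNVs and mosaic
    arms per the config; then artifact structures when enabled.
    """
    validate_marker_map(markers)
    samples = _build_samples(config)
    n_s, n_m = len(samples), len(markers)
    pfb = markers["pfb"].to_numpy(dtype=float)
    is_snp = (markers["probe_class"] == "snp").to_numpy()
    chrom_arr = markers["chrom"].to_numpy()
    arm_arr = markers["arm"].to_numpy()
    mu = np.asarray(config.lrr_means, dtype=float)

    truth_cnvs = _draw_cnv_intervals(markers, config, samples)

    mosaic_rows = []
    for k, entry in enumerate(config.mosaic_arms):
        sample = entry.get("sample", k)
        if isinstance(sample, int):
            sample = samples["sample_id"].iloc[sample]
        mosaic_rows.append({
            "sample_id": sample,
            "chrom": entry.get("chrom", chrom_arr[0]),
            "arm": entry.get("arm", "q"),
            "direction": entry.get("direction", "loss"),
            "fraction": float(entry["fraction"]),
        })
    truth_mosaic = pd.DataFrame(mosaic_rows, columns=[
        "sample_id", "chrom", "arm", "direction", "fraction"])

    lrr = np.empty((n_s, n_m))
    baf = np.empty((n_s, n_m))
    emit_xy = config.emit_xy or bool(config.gender_linked)
    x = np.empty((n_s, n_m)) if emit_xy else None
    y = np.empty((n_s, n_m)) if emit_xy else None

    snp_pfb = np.where(is_snp, pfb, 0.0)
    for si in range(n_s):
        rng = np.random.default_rng([config.seed, _STREAM_COHORT, si, 0])
        rec = samples.iloc[si]
        sd = config.lrr_sd
        if rec["dna_source"] == "cell_line" and config.lrr_sd_cell_line:
            sd = config.lrr_sd_cell_line
        lrr_i = rng.normal(0.0, sd, size=n_m)
        geno = rng.binomial(2, snp_pfb)
        baf_i = np.clip(geno / 2.0 + rng.normal(0.0, config.baf_sd, n_m), 0, 1)
        baf_i[~is_snp] = np.nan

        # germline CNVs
        mine = truth_cnvs[truth_cnvs["sample_id"] == rec["sample_id"]]
        for _, cv in mine.iterrows():
            span = _marker_span(markers, cv["chrom"],
                                cv["start_pos"], cv["end_pos"])
            c = int(cv["cn"])
            lrr_i[span] += mu[c]
            if c == 0:
                baf_i[span] = rng.uniform(0, 1, size=len(span))
            else:
                b = rng.binomial(c, snp_pfb[span])
                baf_i[span] = np.clip(
                    b / c + rng.normal(0.0, config.baf_sd, len(span)), 0, 1)
            baf_i[span[~is_snp[span]]] = np.nan

        # mosaic arms
        mine_m = truth_mosaic[truth_mosaic["sample_id"] == rec["sample_id"]]
        for _, mo in mine_m.iterrows():
            span = np.flatnonzero((chrom_arr == mo["chrom"])
                                  & (arm_arr == mo["arm"]))
            f = float(mo["fraction"])
            c = 1 if mo["direction"] == "loss" else 3
            lrr_i[span] += f * mu[c]
            lo, hi = (_loss_bands(f) if mo["direction"] == "loss"
                      else _gain_bands(f))
            g = geno[span]
            centers = np.where(g == 0, 0.0, np.where(g == 2, 1.0, 0.5))
            het = g == 1
            side = rng.random(len(span)) < 0.5
            centers = np.where(het, np.where(side, lo, hi), centers)
            baf_i[span] = np.clip(
                centers + rng.normal(0.0, config.baf_sd, len(span)), 0, 1)
            baf_i[span[~is_snp[span]]] = np.nan

        lrr[si] = lrr_i
        baf[si] = baf_i
        if emit_xy:
            theta_c = np.where(is_snp,
                               np.choose(geno, [0.08, 0.5, 0.92]), 0.5)
            theta = np.clip(
                theta_c + rng.normal(0.0, 0.03, n_m), 0.001, 0.999)
            r = config.intensity_scale * np.exp2(lrr_i)
            ang = theta * (np.pi / 2)
            x[si] = r * np.cos(ang)
            y[si] = r * np.sin(ang)

    panel = IntensityPanel(markers=markers.copy(), samples=list(
        samples["sample_id"]), lrr=lrr, baf=baf, x=x, y=y)
    truth = TruthSet(
        germline_cnvs=truth_cnvs,
        mosaic_arms=truth_mosaic,
        gender_linked_markers=pd.DataFrame(columns=["marker_id", "pattern"]),
    )
    if config.gender_linked or config.vntr_enabled or config.loh_enabled:
        panel, truth = inject_artifacts(panel, samples, truth, config)
    return panel, samples, truth


def inject_artifacts(
    panel: IntensityPanel, samples: pd.DataFrame, truth: TruthSet,
    config: SimConfig,
) -> tuple[IntensityPanel, TruthSet]:
    """Overwrite selected markers with artifact signal structures.

    Three structures are supported: sex-cross-hybridizing markers
    (patterns B/C/D), a monomorphic VNTR probe group with a DNA-source
    batch shift, and a rare-haplotype low-MAF SNP block producing
    LOH-like BAF.  Marker PFB entries for the LOH block are written as
    ``loh_reported_pfb`` (the value a caller would assume), while the
    generative haplotype frequency is recorded in the truth set.
    """
    markers = panel.markers.copy()
    lrr, baf = panel.lrr.copy(), panel.baf.copy()
    x = None if panel.x is None else panel.x.copy()
    y = None if panel.y is None else panel.y.copy()
    pick = np.random.default_rng([config.seed, _STREAM_ARTIFACT_PICK])
    is_snp = (markers["probe_class"] == "snp").to_numpy()
    unstable = markers["unstable_region"].to_numpy()
    male = (samples["sex"] == "male").to_numpy()
    cell = (samples["dna_source"] == "cell_line").to_numpy()
    used = np.zeros(len(markers), dtype=bool)
    n_s = panel.n_samples

    def srng(si: int, tag: int) -> np.random.Generator:
        return np.random.default_rng(
            [config.seed, _STREAM_ARTIFACT_SAMPLE, si, tag])

    gl_rows = []
    for pattern, count in sorted(config.gender_linked.items()):
        if pattern not in {"B", "C", "D"}:
            raise ConfigError(f"unknown gender-linked pattern {pattern}")
        want_snp = pattern != "C"
        eligible = np.flatnonzero((is_snp == want_snp) & ~unstable & ~used)
        if len(eligible) < count:
            raise ConfigError(
                f"not enough eligible markers for pattern {pattern}")
        chosen = np.sort(pick.choice(eligible, size=count, replace=False))
        used[chosen] = True
        for j in chosen:
            gl_rows.append({"marker_id": markers["marker_id"].iloc[j],
                            "pattern": pattern})
        for si in range(n_s):
            rng = srng(si, ord(pattern))
            nz = config.baf_sd
            if pattern == "B":
                # complete co-hybridization: the two sexes land in
                # disjoint BAF clusters (hom-like vs het-like)
                if male[si]:
                    baf[si, chosen] = np.clip(
                        0.5 + rng.normal(0, nz, count), 0, 1)
                    tc = 0.5
                else:
                    allele = rng.random(count) < 0.5
                    baf[si, chosen] = np.clip(
                        allele.astype(float) + rng.normal(0, nz, count), 0, 1)
                    tc = np.where(allele, 0.92, 0.08)
                if x is not None:
                    theta = np.clip(tc + rng.normal(0, 0.02, count),
                                    0.001, 0.999)
                    r = config.intensity_scale * np.exp2(lrr[si, chosen])
                    x[si, chosen] = r * np.cos(theta * np.pi / 2)
                    y[si, chosen] = r * np.sin(theta * np.pi / 2)
            elif pattern == "C":
                # monomorphic probe, sexes separated in Theta only;
                # LRR means do not differ by sex
                baf[si, chosen] = np.nan
                tc = 0.3 if male[si] else 0.7
                if x is not None:
                    theta = np.clip(tc + rng.normal(0, 0.03, count),
                                    0.001, 0.999)
                    r = config.intensity_scale * np.exp2(lrr[si, chosen])
                    x[si, chosen] = r * np.cos(theta * np.pi / 2)
                    y[si, chosen] = r * np.sin(theta * np.pi / 2)
            else:  # pattern D: partial hybridization, sex-shifted clusters
                p = markers["pfb"].to_numpy()[chosen]
                g = rng.binomial(2, p)
                centers = g / 2.0
                shift = 3.0 * config.lrr_sd if male[si] else 0.0
                lrr[si, chosen] = lrr[si, chosen] + shift
                baf[si, chosen] = np.clip(
                    centers + rng.normal(0, nz, count), 0, 1)
                if x is not None:
                    tc = np.choose(g, [0.08, 0.5, 0.92])
                    tc = tc + (0.15 if male[si] else 0.0)
                    theta = np.clip(tc + rng.normal(0, 0.03, count),
                                    0.001, 0.999)
                    r = config.intensity_scale * np.exp2(lrr[si, chosen])
                    x[si, chosen] = r * np.cos(theta * np.pi / 2)
                    y[si, chosen] = r * np.sin(theta * np.pi / 2)
    gender_df = pd.DataFrame(gl_rows, columns=["marker_id", "pattern"])

    vntr_info = truth.vntr
    if config.vntr_enabled:
        eligible = np.flatnonzero(~unstable & ~used)
        if len(eligible) < config.vntr_n_probes:
            raise ConfigError("no room for the VNTR probe group")
        # an adjacent run of probes, all tagging the same repeat
        runs = [eligible[k:k + config.vntr_n_probes]
                for k in range(len(eligible) - config.vntr_n_probes + 1)
                if np.all(np.diff(eligible[k:k + config.vntr_n_probes]) == 1)]
        if not runs:
            raise ConfigError("no adjacent marker run for the VNTR group")
        group = runs[int(pick.integers(0, len(runs)))]
        used[group] = True
        markers.loc[group, "probe_class"] = "cnv_probe"
        markers.loc[group, "pfb"] = PFB_MONOMORPHIC
        ref2 = 2 * config.vntr_ref_repeats
        summed = np.empty(n_s, dtype=int)
        for si in range(n_s):
            rng = srng(si, 100)
            alleles = config.vntr_ref_repeats + rng.integers(
                -config.vntr_repeat_spread, config.vntr_repeat_spread + 1,
                size=2)
            summed[si] = int(alleles.sum())
            # batch offset for cell-line DNA; normalisation is anchored
            # to reference clusters, so the offset is not re-centred
            shift = config.vntr_source_shift if cell[si] else 0.0
            center = config.vntr_slope * (summed[si] - ref2) / ref2 + shift
            lrr[si, group] = center + rng.normal(
                0, config.lrr_sd, len(group))
            baf[si, group] = np.nan
        vntr_info = {
            "probe_ids": markers["marker_id"].iloc[group].tolist(),
            "ref_repeats": config.vntr_ref_repeats,
            "summed_repeats": pd.Series(
                summed, index=samples["sample_id"].tolist()),
            "slope": config.vntr_slope,
            "source_shift": config.vntr_source_shift,
        }

    loh_info = truth.loh
    if config.loh_enabled:
        eligible = np.flatnonzero(is_snp & ~unstable & ~used)
        # a strictly adjacent SNP run: interspersed monomorphic probes
        # would break up the homozygous stretch the block emulates
        runs = [eligible[k:k + config.loh_n_snps]
                for k in range(len(eligible) - config.loh_n_snps + 1)
                if np.all(np.diff(eligible[k:k + config.loh_n_snps])
                          == 1)]
        if not runs:
            raise ConfigError("no adjacent SNP run for the LOH block")
        block = runs[int(pick.integers(0, len(runs)))]
        used[block] = True
        markers.loc[block, "pfb"] = config.loh_reported_pfb
        h = config.loh_hap_freq
        eps = config.loh_background_minor
        n_hap = np.empty(n_s, dtype=int)
        for si in range(n_s):
            rng = srng(si, 200)
            n_hap[si] = rng.binomial(2, h)
            dosage = n_hap[si] + rng.binomial(2 - n_hap[si],
                                              eps, size=len(block))
            baf[si, block] = np.clip(
                dosage / 2.0 + rng.normal(0, config.baf_sd, len(block)),
                0, 1)
            lrr[si, block] = lrr[si, block] + config.loh_lrr_bias
        loh_info = {
            "snp_ids": markers["marker_id"].iloc[block].tolist(),
            "hap_freq": h,
            "true_pfb": h + (1 - h) * eps,
            "n_hap": pd.Series(n_hap, index=samples["sample_id"].tolist()),
        }

    panel2 = IntensityPanel(markers=markers,
                            samples=list(panel.samples),
                            lrr=lrr, baf=baf, x=x, y=y)
    truth2 = TruthSet(
        germline_cnvs=truth.germline_cnvs,
        mosaic_arms=truth.mosaic_arms,
        gender_linked_markers=gender_df if len(gl_rows)
        else truth.gender_linked_markers,
        vntr=vntr_info,
        loh=loh_info,
    )
    return panel2, truth2
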