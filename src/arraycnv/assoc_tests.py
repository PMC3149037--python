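"""Case-control carrier association with permutation-based significance.

A sample *carries* a locus when at least one retained CNV call overlaps
it.  Loci are either single marker positions or 400 kb windows (200 kb
either side of every marker); adjacent loci with identical carrier sets
are collapsed into one record, which leaves results unchanged but keeps
the permutation cost proportional to the number of distinct loci.

The per-locus statistic is the one-sided Fisher exact test for case
excess (hypergeometric tail), with the odds ratio ad/bc reported
alongside.  Genome-wide significance is empirical max-T: affection
labels are permuted preserving group sizes, the full scan is repeated,
and the genome-wide minimum nominal p is recorded; a locus's empirical
p is (1 + #{permutations with min p <= observed p}) / (B + 1).  With
``permutations="exhaustive"`` all distinct label assignments are
enumerated instead (p = #{min p <= observed} / n_assignments).

Candidate-locus replication applies the gene-overlap carrier
definition with compound-heterozygote exclusion: samples with two or
more distinct calls at the locus are removed from both margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import ArrayCnvError

__all__ = [
    "ContingencyTable",
    "fisher_one_sided",
    "odds_ratio",
    "carrier_status",
    "scan",
    "maxT_genomewide",
    "study_wide_correction",
    "replicate_locus",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: a/b case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ArrayCnvError("negative cell count")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


def fisher_one_sided(table: ContingencyTable) -> float:
    """One-sided Fisher exact p for case excess: P(X >= a | margins)."""
    m = table.n_cases + table.n_controls
    if m == 0:
        return 1.0
    k = table.a + table.c          # total carriers
    return float(hypergeom.sf(table.a - 1, m, k, table.n_cases))


def odds_ratio(table: ContingencyTable) -> float:
    """ad/bc; inf when the denominator is zero with a positive numerator,
    NaN for the all-zero-margin table."""
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def _overlap_counts(calls: pd.DataFrame, samples: pd.DataFrame,
                    chrom: str, start: int, end: int) -> pd.Series:
    """Number of distinct calls per sample overlapping [start, end]."""
    counts = pd.Series(0, index=samples["sample_id"].tolist())
    if calls.empty:
        return counts
    sub = calls[(calls["chrom"] == chrom)
                & (calls["start_pos"] <= end)
                & (calls["end_pos"] >= start)]
    for sid, n in sub.groupby("sample_id").size().items():
        if sid in counts.index:
            counts[sid] += int(n)
    return counts


def carrier_status(calls: pd.DataFrame, samples: pd.DataFrame,
                   locus: tuple[str, int, int],
                   exclude_compound_hets: bool = False,
                   known_chroms: set[str] | None = None,
                   ) -> tuple[ContingencyTable, list[str]]:
    """Carrier table at one locus; optionally drop compound heterozygotes.

    ``locus`` is (chrom, start, end), 1-based inclusive.  Samples with
    two or more distinct overlapping calls are removed from both margins
    when ``exclude_compound_hets`` is set; their ids are returned.
    """
    chrom, start, end = locus
    if known_chroms is not None and chrom not in known_chroms:
        raise ArrayCnvError(f"locus on unknown chromosome {chrom}")
    counts = _overlap_counts(calls, samples, chrom, start, end)
    phen = samples.set_index("sample_id")["phenotype"]
    dropped: list[str] = []
    if exclude_compound_hets:
        dropped = counts.index[counts >= 2].tolist()
    use = ~counts.index.isin(dropped)
    carrier = counts[use] >= 1
    is_case = (phen[counts.index[use]] == "case").to_numpy()
    carr = carrier.to_numpy()
    return ContingencyTable(
        a=int((carr & is_case).sum()),
        b=int((~carr & is_case).sum()),
        c=int((carr & ~is_case).sum()),
        d=int((~carr & ~is_case).sum()),
    ), dropped


# ------------------------------------------------------------------ scan

def _locus_matrix(calls: pd.DataFrame, samples: pd.DataFrame,
                  markers: pd.DataFrame, mode: str,
                  half_width: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Distinct loci and the per-sample overlapping-call count matrix.

    Returns (loci frame with chrom/start/end span of the collapsed run,
    counts of shape (n_loci, n_samples)).
    """
    if mode not in {"position", "window"}:
        raise ArrayCnvError(f"unknown scan mode {mode!r}")
    hw = int(half_width) if mode == "window" else 0
    sample_ids = samples["sample_id"].tolist()
    s_index = {s: i for i, s in enumerate(sample_ids)}
    loci_rows: list[dict] = []
    mats: list[np.ndarray] = []
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        counts = np.zeros((len(pos), len(sample_ids)), dtype=np.int16)
        sub = calls[calls["chrom"] == chrom]
        for _, r in sub.iterrows():
            si = s_index.get(r["sample_id"])
            if si is None:
                continue
            lo = np.searchsorted(pos, r["start_pos"] - hw, side="left")
            hi = np.searchsorted(pos, r["end_pos"] + hw, side="right")
            counts[lo:hi, si] += 1
        # collapse adjacent markers with identical per-sample counts
        j = 0
        while j < len(pos):
            k = j
            while k + 1 < len(pos) and np.array_equal(counts[k + 1],
                                                      counts[j]):
                k += 1
            if counts[j].any():
                loci_rows.append({
                    "chrom": chrom,
                    "locus_start": int(pos[j]) - hw,
                    "locus_end": int(pos[k]) + hw,
                    "n_marker_loci": k - j + 1,
                })
                mats.append(counts[j])
            j = k + 1
    loci = pd.DataFrame(loci_rows, columns=[
        "chrom", "locus_start", "locus_end", "n_marker_loci"])
    mat = (np.vstack(mats) if mats
           else np.zeros((0, len(sample_ids)), dtype=np.int16))
    return loci, mat


def _tables_from_matrix(mat: np.ndarray, is_case: np.ndarray,
                        exclude_compound_hets: bool
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                   np.ndarray]:
    """Per-locus (a, k, n_case, m) vectors given a label assignment."""
    carrier = mat >= 1
    if exclude_compound_hets:
        retained = mat < 2
    else:
        retained = np.ones_like(carrier, dtype=bool)
    carr = carrier & retained
    a = carr @ is_case.astype(np.int64)
    k = carr.sum(axis=1)
    n_case = retained @ is_case.astype(np.int64)
    m = retained.sum(axis=1)
    return a, k, n_case, m


def _vector_p(a: np.ndarray, k: np.ndarray, n_case: np.ndarray,
              m: np.ndarray) -> np.ndarray:
    return hypergeom.sf(a - 1, m, k, n_case)


def scan(calls: pd.DataFrame, samples: pd.DataFrame,
         markers: pd.DataFrame, mode: str = "position",
         half_width: int = 200_000,
         exclude_compound_hets: bool = False) -> pd.DataFrame:
    """Carrier association at every distinct locus of the genome.

    Returns one row per collapsed locus with the carrier table, odds
    ratio and one-sided nominal p.  Loci where no sample carries a call
    are omitted (their p is 1 by construction).
    """
    loci, mat = _locus_matrix(calls, samples, markers, mode, half_width)
    is_case = (samples["phenotype"] == "case").to_numpy()
    a, k, n_case, m = _tables_from_matrix(mat, is_case,
                                          exclude_compound_hets)
    p = _vector_p(a, k, n_case, m) if len(a) else np.zeros(0)
    out = loci.copy()
    out["case_carriers"] = a
    out["case_total"] = n_case
    out["control_carriers"] = k - a
    out["control_total"] = m - n_case
    out["odds_ratio"] = [
        odds_ratio(ContingencyTable(int(ai), int(ni - ai),
                                    int(ki - ai),
                                    int(mi - ni - ki + ai)))
        for ai, ki, ni, mi in zip(a, k, n_case, m)]
    out["p_nominal"] = p
    out["mode"] = mode
    return out


def maxT_genomewide(calls: pd.DataFrame, samples: pd.DataFrame,
                    markers: pd.DataFrame, mode: str = "position",
                    half_width: int = 200_000,
                    n_permutations: int | str = 1000,
                    seed: int = 0,
                    exclude_compound_hets: bool = False) -> pd.DataFrame:
    """Scan plus empirical genome-wide p by max-T label permutation.

    Each permutation shuffles affection status (group sizes preserved),
    recomputes every locus's nominal p and records the genome-wide
    minimum.  ``n_permutations="exhaustive"`` enumerates all
    case-position assignments instead (only sensible for tiny cohorts).
    """
    loci, mat = _locus_matrix(calls, samples, markers, mode, half_width)
    is_case = (samples["phenotype"] == "case").to_numpy()
    res = scan(calls, samples, markers, mode, half_width,
               exclude_compound_hets)
    if res.empty:
        res["p_genomewide"] = pd.Series(dtype=float)
        return res
    obs_p = res["p_nominal"].to_numpy()
    n_s = len(is_case)
    n_case = int(is_case.sum())

    def min_p_for(labels: np.ndarray) -> float:
        a, k, nc, m = _tables_from_matrix(mat, labels,
                                          exclude_compound_hets)
        return float(np.min(_vector_p(a, k, nc, m)))

    if n_permutations == "exhaustive":
        mins = []
        for case_pos in combinations(range(n_s), n_case):
            labels = np.zeros(n_s, dtype=bool)
            labels[list(case_pos)] = True
            mins.append(min_p_for(labels))
        mins = np.asarray(mins)
        emp = np.array([(mins <= p + 1e-12).mean() for p in obs_p])
    else:
        b = int(n_permutations)
        if b < 1:
            raise ArrayCnvError("need at least one permutation")
        rng = np.random.default_rng(seed)
        mins = np.empty(b)
        for t in range(b):
            mins[t] = min_p_for(rng.permutation(is_case))
        emp = np.array([(1 + (mins <= p + 1e-12).sum()) / (b + 1)
                        for p in obs_p])
    res["p_genomewide"] = emp
    return res


def study_wide_correction(results: list[pd.DataFrame],
                          alpha: float = 0.05) -> list[pd.DataFrame]:
    """Flag study-wide significance across analysis approaches.

    With ``n`` approaches a locus is study-wide significant when its
    empirical genome-wide p is strictly below ``alpha / n``.
    """
    n = len(results)
    if n < 1:
        raise ArrayCnvError("need at least one approach")
    threshold = alpha / n
    out = []
    for df in results:
        d = df.copy()
        d["study_wide_threshold"] = threshold
        d["study_wide_significant"] = d["p_genomewide"] < threshold
        out.append(d)
    return out


def replicate_locus(calls: pd.DataFrame, samples: pd.DataFrame,
                    gene_interval: tuple[str, int, int]) -> dict:
    """Candidate-gene carrier test with compound-heterozygote exclusion.

    Carriers are samples with exactly one retained call overlapping any
    portion of the gene; samples with two or more are excluded from
    both margins.  Returns the table, odds ratio, one-sided Fisher p
    and the excluded sample ids.
    """
    table, dropped = carrier_status(calls, samples, gene_interval,
                                    exclude_compound_hets=True)
    return {
        "locus": gene_interval,
        "table": table,
        "odds_ratio": odds_ratio(table),
        "p_one_sided": fisher_one_sided(table),
        "compound_het_excluded": dropped,
    }
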