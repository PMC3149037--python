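"""CNV call filter sets and their accounting.

Three complementary filters reduce false-positive calls:

* **Conservative** — large events: span >= ``min_length_bp`` (default
  100 kb) and >= ``min_markers_conservative`` (default 20) markers.
* **Common** — recurrent events: span >= 5 markers and cover at least
  one probe seen deleted or duplicated >= 3 times across the cohort.
* **Gene-centric** — the subset of the Conservative/Common union that
  overlaps at least one annotated gene by >= 1 bp (no exon requirement).

The recurrence count pools deletions and duplications by default; a
direction-specific mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FormatError, validate_callset

__all__ = [
    "FilterThresholds",
    "probe_recurrence",
    "classify_calls",
    "filter_accounting",
    "select_set",
]


@dataclass(frozen=True)
class FilterThresholds:
    min_length_bp: int = 100_000
    min_markers_conservative: int = 20
    min_markers_common: int = 5
    min_recurrence: int = 3
    pool_directions: bool = True


def _covered_markers(calls: pd.DataFrame,
                     markers: pd.DataFrame) -> list[np.ndarray]:
    """Marker indices covered by each call (positions, per chromosome)."""
    pos_by_chrom = {c: grp["pos"].to_numpy()
                    for c, grp in markers.groupby("chrom", sort=False)}
    idx_by_chrom = {c: np.flatnonzero((markers["chrom"] == c).to_numpy())
                    for c in pos_by_chrom}
    out = []
    for _, r in calls.iterrows():
        pos = pos_by_chrom.get(r["chrom"])
        if pos is None:
            out.append(np.array([], dtype=int))
            continue
        lo = np.searchsorted(pos, r["start_pos"], side="left")
        hi = np.searchsorted(pos, r["end_pos"], side="right")
        out.append(idx_by_chrom[r["chrom"]][lo:hi])
    return out


def probe_recurrence(calls: pd.DataFrame,
                     markers: pd.DataFrame) -> pd.DataFrame:
    """Per-marker counts of deletion and duplication events.

    Every marker inside a call increments the direction-specific counter
    once per call (a sample contributes once per event).  A call that
    covers no marker indicates corrupt input and is rejected.
    """
    validate_callset(calls)
    n_del = np.zeros(len(markers), dtype=int)
    n_dup = np.zeros(len(markers), dtype=int)
    for (_, r), cov in zip(calls.iterrows(),
                           _covered_markers(calls, markers)):
        if len(cov) == 0:
            raise FormatError(
                f"call {r['sample_id']} {r['chrom']}:{r['start_pos']}-"
                f"{r['end_pos']} spans zero markers")
        if r["cn"] < 2:
            n_del[cov] += 1
        else:
            n_dup[cov] += 1
    return pd.DataFrame({"marker_id": markers["marker_id"],
                         "n_deleted": n_del, "n_duplicated": n_dup})


def _gene_overlap(calls: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(len(calls), dtype=bool)
    if genes is None or len(genes) == 0:
        return hit
    for _, g in genes.iterrows():
        hit |= ((calls["chrom"] == g["chrom"])
                & (calls["start_pos"] <= g["end_pos"])
                & (calls["end_pos"] >= g["start_pos"])).to_numpy()
    return hit


def classify_calls(calls: pd.DataFrame, markers: pd.DataFrame,
                   genes: pd.DataFrame | None = None,
                   thresholds: FilterThresholds | None = None,
                   recurrence: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annotate each call with its filter-set membership.

    Returns the callset with boolean columns ``conservative``,
    ``common``, ``in_union`` and ``gene_centric`` added.  The recurrence
    table defaults to one computed over this same callset.
    """
    th = thresholds or FilterThresholds()
    out = calls.reset_index(drop=True).copy()
    if recurrence is None:
        recurrence = probe_recurrence(out, markers)
    n_del = recurrence["n_deleted"].to_numpy()
    n_dup = recurrence["n_duplicated"].to_numpy()
    conservative = ((out["length_bp"] >= th.min_length_bp)
                    & (out["n_markers"] >= th.min_markers_conservative)
                    ).to_numpy()
    common = np.zeros(len(out), dtype=bool)
    covered = _covered_markers(out, markers)
    for i, (idx, cov) in enumerate(zip(out.index, covered)):
        if out.at[idx, "n_markers"] < th.min_markers_common or not len(cov):
            continue
        if th.pool_directions:
            best = int(np.max(n_del[cov] + n_dup[cov]))
        else:
            rec = n_del if out.at[idx, "cn"] < 2 else n_dup
            best = int(np.max(rec[cov]))
        common[i] = best >= th.min_recurrence
    out["conservative"] = conservative
    out["common"] = common
    out["in_union"] = conservative | common
    out["gene_centric"] = out["in_union"].to_numpy() \
        & _gene_overlap(out, genes)
    return out


def filter_accounting(memberships: pd.DataFrame) -> dict:
    """Counts, percentages and rejected-call size histogram.

    Expects the boolean membership columns of :func:`classify_calls`.
    The histogram bins unanalyzed calls (in neither filter) by marker
    count: 5-9, 10-14, 15-19 and >= 20 markers, with mean bp size.
    """
    n = len(memberships)
    cons = int(memberships["conservative"].sum())
    comm = int(memberships["common"].sum())
    inter = int((memberships["conservative"]
                 & memberships["common"]).sum())
    union = int(memberships["in_union"].sum())
    gene = int(memberships["gene_centric"].sum())
    rejected = memberships[~memberships["in_union"]]
    bins = {"5-9": (5, 9), "10-14": (10, 14),
            "15-19": (15, 19), ">=20": (20, np.inf)}
    hist = {}
    for name, (lo, hi) in bins.items():
        sub = rejected[(rejected["n_markers"] >= lo)
                       & (rejected["n_markers"] <= hi)]
        hist[name] = {"n": len(sub),
                      "mean_size_bp": float(sub["length_bp"].mean())
                      if len(sub) else float("nan")}

    def pct(k: int) -> float:
        return round(100.0 * k / n, 1) if n else 0.0

    return {
        "total": n,
        "conservative": cons, "pct_conservative": pct(cons),
        "common": comm, "pct_common": pct(comm),
        "intersection": inter,
        "union": union,
        "unanalyzed": n - union, "pct_unanalyzed": pct(n - union),
        "gene_centric": gene,
        "pct_gene_centric_of_union":
            round(100.0 * gene / union, 1) if union else 0.0,
        "rejected_histogram": hist,
    }


def select_set(memberships: pd.DataFrame, which: str) -> pd.DataFrame:
    """Subset a classified callset to one filter set."""
    col = {"conservative": "conservative", "common": "common",
           "union": "in_union", "gene": "gene_centric",
           "gene_centric": "gene_centric"}.get(which)
    if col is None:
        raise FormatError(f"unknown filter set {which!r}")
    return memberships[memberships[col]].reset_index(drop=True)
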