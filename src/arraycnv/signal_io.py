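"""Readers and writers for every on-disk format, plus pipeline config.

All files are tab-separated text with explicit headers.  The signal file
follows the array-software column layout: marker columns ``Name``,
``Chr``, ``Position`` followed by per-sample column pairs
``<sample>.Log R Ratio`` and ``<sample>.B Allele Freq`` (optionally
``<sample>.X`` / ``<sample>.Y`` raw intensities).  Internal coordinates
are 1-based inclusive; BED import/export converts to/from 0-based
half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import (
    CALL_COLUMNS,
    FormatError,
    ConfigError,
    IntensityPanel,
    SAMPLE_COLUMNS,
    empty_callset,
    validate_callset,
    validate_marker_map,
    validate_samples,
)

LRR_SUFFIX = ".Log R Ratio"
BAF_SUFFIX = ".B Allele Freq"
X_SUFFIX = ".X"
Y_SUFFIX = ".Y"


# ---------------------------------------------------------------- signal

def write_signal(panel: IntensityPanel, path: str | Path) -> None:
    """Write a panel in the per-sample paired-column signal layout."""
    cols: dict[str, Any] = {
        "Name": panel.markers["marker_id"],
        "Chr": panel.markers["chrom"],
        "Position": panel.markers["pos"],
    }
    for i, s in enumerate(panel.samples):
        cols[f"{s}{LRR_SUFFIX}"] = panel.lrr[i]
        cols[f"{s}{BAF_SUFFIX}"] = panel.baf[i]
        if panel.x is not None:
            cols[f"{s}{X_SUFFIX}"] = panel.x[i]
            cols[f"{s}{Y_SUFFIX}"] = panel.y[i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, na_rep="NA",
                              float_format="%.6g")


def read_signal(path: str | Path,
                markers: pd.DataFrame | None = None) -> IntensityPanel:
    """Read a signal file into a panel.

    Marker metadata absent from the file (arm, probe class, PFB) is taken
    from ``markers`` when given, else defaulted (arm from position order
    is not recoverable, so a single ``q`` arm is assumed and PFB is set
    to 0.5 for every marker).  Missing values are tolerated and masked.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("Name", "Chr", "Position"):
        if col not in df.columns:
            raise FormatError(f"signal file missing column {col}")
    if df["Name"].duplicated().any():
        dup = df.loc[df["Name"].duplicated(), "Name"].iloc[0]
        raise FormatError(f"duplicated marker id: {dup}")
    sample_ids: list[str] = []
    for col in df.columns:
        if col.endswith(LRR_SUFFIX):
            sample_ids.append(col[: -len(LRR_SUFFIX)])
    for s in sample_ids:
        if f"{s}{BAF_SUFFIX}" not in df.columns:
            raise FormatError(f"sample {s} lacks a '{BAF_SUFFIX}' column")
    lrr = np.vstack([df[f"{s}{LRR_SUFFIX}"].to_numpy(float)
                     for s in sample_ids])
    baf = np.vstack([df[f"{s}{BAF_SUFFIX}"].to_numpy(float)
                     for s in sample_ids])
    with np.errstate(invalid="ignore"):
        bad = (baf < -1e-6) | (baf > 1 + 1e-6)
    if np.any(np.nan_to_num(bad)):
        j = int(np.argwhere(np.nan_to_num(bad))[0][1])
        raise FormatError(f"BAF outside [0,1] at marker {df['Name'].iloc[j]}")
    baf = np.clip(baf, 0.0, 1.0)
    have_xy = all(f"{s}{X_SUFFIX}" in df.columns
                  and f"{s}{Y_SUFFIX}" in df.columns for s in sample_ids)
    x = y = None
    if have_xy and sample_ids:
        x = np.vstack([df[f"{s}{X_SUFFIX}"].to_numpy(float)
                       for s in sample_ids])
        y = np.vstack([df[f"{s}{Y_SUFFIX}"].to_numpy(float)
                       for s in sample_ids])
    if markers is not None:
        mk = markers.reset_index(drop=True)
        if not (mk["marker_id"].to_numpy() == df["Name"].to_numpy()).all():
            raise FormatError("marker map does not match signal file order")
    else:
        mk = pd.DataFrame({
            "marker_id": df["Name"].astype(str),
            "chrom": df["Chr"].astype(str),
            "arm": "q",
            "pos": df["Position"].astype(np.int64),
            "probe_class": "snp",
            "pfb": 0.5,
            "unstable_region": False,
            "gender_linked": False,
        })
    validate_marker_map(mk)
    return IntensityPanel(markers=mk, samples=sample_ids,
                          lrr=lrr, baf=baf, x=x, y=y)


# ------------------------------------------------------------ small TSVs

def write_pfb(markers: pd.DataFrame, path: str | Path) -> None:
    markers[["marker_id", "chrom", "pos", "pfb"]].rename(columns={
        "marker_id": "Name", "chrom": "Chr", "pos": "Position",
        "pfb": "PFB"}).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def read_pfb(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("Name", "Chr", "Position", "PFB"):
        if col not in df.columns:
            raise FormatError(f"PFB table missing column {col}")
    return df.rename(columns={"Name": "marker_id", "Chr": "chrom",
                              "Position": "pos", "PFB": "pfb"})


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    validate_samples(samples)[SAMPLE_COLUMNS].to_csv(path, sep="\t",
                                                     index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    return validate_samples(pd.read_csv(path, sep="\t"))


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    validate_callset(calls)[CALL_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return empty_callset()
    return validate_callset(df)


def write_truth(truth, path_prefix: str | Path) -> None:
    """Write ground-truth tables as TSVs under a common prefix."""
    prefix = Path(path_prefix)
    truth.germline_cnvs.to_csv(f"{prefix}.cnvs.tsv", sep="\t", index=False)
    truth.mosaic_arms.to_csv(f"{prefix}.mosaic.tsv", sep="\t", index=False)
    truth.gender_linked_markers.to_csv(
        f"{prefix}.gender_linked.tsv", sep="\t", index=False)


# ------------------------------------------------------------------- BED

def write_calls_bed(calls: pd.DataFrame, path: str | Path) -> None:
    """Export calls as BED (0-based half-open); name = sample:cn:conf."""
    validate_callset(calls)
    with open(path, "w") as fh:
        fh.write("# arraycnv calls; name=sample:cn:confidence\n")
        for _, r in calls.iterrows():
            name = f"{r['sample_id']}:{int(r['cn'])}:{r['confidence']:.2f}"
            fh.write(f"{r['chrom']}\t{int(r['start_pos']) - 1}"
                     f"\t{int(r['end_pos'])}\t{name}\n")


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED interval file into 1-based inclusive intervals.

    Returns columns chrom, start_pos, end_pos, name.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"malformed BED line {lineno}")
            try:
                start = int(parts[1])
                end = int(parts[2])
            except ValueError:
                raise FormatError(f"malformed BED line {lineno}") from None
            if start < 0 or end <= start:
                raise FormatError(f"malformed BED line {lineno}")
            name = parts[3] if len(parts) > 3 else f"region_{lineno}"
            rows.append({"chrom": parts[0], "start_pos": start + 1,
                         "end_pos": end, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start_pos", "end_pos",
                                       "name"])


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, r in genes.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start_pos']) - 1}"
                     f"\t{int(r['end_pos'])}\t{r.get('name', '.')}\n")


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Structured configuration for CLI runs; unknown keys are rejected."""

    signal: str | None = None
    pfb: str | None = None
    samples: str | None = None
    genes: str | None = None
    unstable_regions: str | None = None
    caller: dict[str, Any] = field(default_factory=dict)
    filters: dict[str, Any] = field(default_factory=dict)
    association: dict[str, Any] = field(
        default_factory=lambda: {"half_width": 200_000,
                                 "permutations": 1000, "seed": 0})
    diagnostics: dict[str, Any] = field(default_factory=dict)
    simulation: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        assoc = dict(cfg.association)
        assoc.setdefault("half_width", 200_000)
        assoc.setdefault("permutations", 1000)
        assoc.setdefault("seed", 0)
        cfg.association = assoc
        return cfg
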