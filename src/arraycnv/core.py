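"""Core containers shared by every stage of the pipeline.

The pipeline operates on three tabular objects: a *marker map* (the array
manifest: one row per probe, ordered by genomic position), a *sample table*
(one row per individual with sex, phenotype and DNA source), and an
*intensity panel* (per-sample Log R Ratio and B Allele Frequency matrices
aligned to the marker map).  CNV calls are kept in a flat DataFrame, one row
per contiguous non-diploid marker run.

Coordinates are 1-based inclusive throughout (array-manifest convention);
BED import/export converts at the boundary in :mod:`arraycnv.signal_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel population-B-allele frequency marking a monomorphic copy-number
#: probe (no polymorphic BAF signal; the caller uses LRR only there).
PFB_MONOMORPHIC = 2.0

#: Default LRR emission means for copy numbers 0..4 (log2-ratio scale).
LRR_MEANS = (-3.5, -0.66, 0.0, 0.40, 0.68)

MARKER_COLUMNS = [
    "marker_id", "chrom", "arm", "pos", "probe_class", "pfb",
    "unstable_region", "gender_linked",
]

SAMPLE_COLUMNS = ["sample_id", "sex", "phenotype", "dna_source", "study"]

CALL_COLUMNS = [
    "sample_id", "chrom", "start_pos", "end_pos", "cn",
    "n_markers", "length_bp", "confidence",
]


class ArrayCnvError(Exception):
    """Base error for invalid inputs or configuration."""


class FormatError(ArrayCnvError):
    """A file or table violates its format contract."""


class ConfigError(ArrayCnvError):
    """Invalid or inconsistent configuration."""


def validate_marker_map(markers: pd.DataFrame) -> pd.DataFrame:
    """Check marker-map invariants and return the frame unchanged.

    Positions must be strictly increasing within each chromosome,
    chromosome blocks must be contiguous, marker ids unique, and PFB
    values must lie in [0, 1] or equal the monomorphic sentinel.
    """
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise FormatError(f"marker map missing columns: {missing}")
    if markers["marker_id"].duplicated().any():
        dup = markers.loc[markers["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise FormatError(f"duplicated marker id: {dup}")
    chrom = markers["chrom"].to_numpy()
    seen: set[str] = set()
    prev = None
    for c in chrom:
        if c != prev:
            if c in seen:
                raise FormatError(f"chromosome {c} appears in non-contiguous blocks")
            seen.add(c)
            prev = c
    pos = markers["pos"].to_numpy()
    for c in pd.unique(markers["chrom"]):
        p = pos[chrom == c]
        if not np.all(np.diff(p) > 0):
            raise FormatError(f"positions not strictly increasing on {c}")
    pfb = markers["pfb"].to_numpy(dtype=float)
    bad = ~(((pfb >= 0.0) & (pfb <= 1.0)) | (pfb == PFB_MONOMORPHIC))
    if bad.any():
        raise FormatError(
            f"pfb outside [0,1] and not the monomorphic sentinel at "
            f"{markers.loc[bad, 'marker_id'].iloc[0]}"
        )
    return markers


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        raise FormatError("duplicated sample id")
    bad_sex = set(samples["sex"]) - {"male", "female"}
    if bad_sex:
        raise FormatError(f"unknown sex labels: {bad_sex}")
    bad_ph = set(samples["phenotype"]) - {"case", "control"}
    if bad_ph:
        raise FormatError(f"unknown phenotype labels: {bad_ph}")
    return samples


@dataclass
class IntensityPanel:
    """Per-sample LRR/BAF matrices aligned to a marker map.

    ``lrr`` and ``baf`` have shape (n_samples, n_markers); NaN marks a
    missing/masked value.  ``x``/``y`` optionally hold raw allele
    intensities (needed only by the sex-prediction marker QC).
    """

    markers: pd.DataFrame
    samples: list[str]
    lrr: np.ndarray
    baf: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        validate_marker_map(self.markers)
        n_s, n_m = len(self.samples), len(self.markers)
        for name in ("lrr", "baf"):
            mat = getattr(self, name)
            if mat.shape != (n_s, n_m):
                raise FormatError(
                    f"{name} matrix shape {mat.shape} != ({n_s}, {n_m})"
                )
        with np.errstate(invalid="ignore"):
            bad = (self.baf < -1e-6) | (self.baf > 1 + 1e-6)
        if np.any(np.nan_to_num(bad)):
            j = int(np.argwhere(np.nan_to_num(bad))[0][1])
            raise FormatError(
                f"BAF outside [0,1] at marker {self.markers['marker_id'].iloc[j]}"
            )
        if (self.x is None) != (self.y is None):
            raise FormatError("x and y must be supplied together")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id}") from None

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous column slice per chromosome, in file order."""
        chrom = self.markers["chrom"].to_numpy()
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                out[str(chrom[start])] = slice(start, i)
                start = i
        return out

    def subset_markers(self, keep: np.ndarray) -> "IntensityPanel":
        """Return a panel restricted to the boolean/index marker mask."""
        markers = self.markers.loc[keep].reset_index(drop=True)
        return IntensityPanel(
            markers=markers,
            samples=list(self.samples),
            lrr=self.lrr[:, keep],
            baf=self.baf[:, keep],
            x=None if self.x is None else self.x[:, keep],
            y=None if self.y is None else self.y[:, keep],
        )


def empty_callset() -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": pd.Series(dtype=str),
        "chrom": pd.Series(dtype=str),
        "start_pos": pd.Series(dtype=np.int64),
        "end_pos": pd.Series(dtype=np.int64),
        "cn": pd.Series(dtype=np.int64),
        "n_markers": pd.Series(dtype=np.int64),
        "length_bp": pd.Series(dtype=np.int64),
        "confidence": pd.Series(dtype=float),
    })


def validate_callset(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise FormatError(f"callset missing columns: {missing}")
    if len(calls):
        if (calls["n_markers"] < 1).any():
            raise FormatError("call with n_markers < 1")
        if (calls["cn"] == 2).any():
            raise FormatError("diploid state is not a call")
        if ((calls["end_pos"] - calls["start_pos"] + 1) != calls["length_bp"]).any():
            raise FormatError("length_bp != end_pos - start_pos + 1")
    return calls
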