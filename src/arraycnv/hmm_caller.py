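"""Hidden-Markov-model CNV segmentation of LRR/BAF tracks.

Five hidden copy-number states (0-4) with state-specific LRR means and a
genotype-mixture BAF emission: at copy number ``c`` the B-allele count
``b`` follows Binomial(c, PFB) and BAF clusters at ``b/c`` with
boundary-censored Gaussian noise; copy number 0 emits uniform BAF;
monomorphic probes (PFB sentinel) contribute LRR only.  Transitions are
distance-dependent: the total probability of leaving a state over a gap
of ``d`` bp is ``lambda_max * (1 - exp(-d/D))``, split equally among the
other four states, so distant markers are nearly uncoupled while dense
markers strongly smooth.

Maximal Viterbi runs of non-diploid state become calls.  A call's
confidence is the summed per-marker emission log-likelihood advantage of
the called state over the diploid state; calls below ``min_confidence``
or shorter than ``min_markers`` markers are discarded.  The ``strict``
and ``lenient`` presets differ in transition rate and confidence gate
and are used to study caller discordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    ArrayCnvError,
    CALL_COLUMNS,
    IntensityPanel,
    LRR_MEANS,
    PFB_MONOMORPHIC,
    empty_callset,
)

_SQRT2PI = math.sqrt(2.0 * math.pi)
_BOUNDARY_EPS = 1e-9     # BAF at/inside this of 0 or 1 counts as censored
_STATE0_BOUNDARY = 1e-3  # boundary atom for the uniform (CN 0) BAF model
_DENSITY_FLOOR = 1e-30


@dataclass(frozen=True)
class HmmParams:
    """Emission/transition parameters and the call gate."""

    lrr_means: tuple[float, ...] = LRR_MEANS
    lrr_sd: float = 0.2
    baf_sd: float = 0.03
    transition_bp: float = 100_000.0   # D: distance scale of decoupling
    lambda_max: float = 1e-3           # asymptotic leave-state probability
    min_markers: int = 5
    min_confidence: float = 10.0
    max_lrr_sd: float | None = None    # drop samples noisier than this
    preset: str = "custom"

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.lrr_means) > 0):
            raise ArrayCnvError("lrr_means must be strictly increasing")
        if not 0 < self.lambda_max < 0.5:
            raise ArrayCnvError("lambda_max must be in (0, 0.5)")
        if self.transition_bp <= 0:
            raise ArrayCnvError("transition_bp must be positive")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "HmmParams":
        if name == "strict":
            base = cls(lambda_max=1e-3, min_confidence=10.0, preset="strict")
        elif name == "lenient":
            base = cls(lambda_max=1e-2, min_confidence=5.0, preset="lenient")
        else:
            raise ArrayCnvError(f"unknown preset {name!r}")
        return replace(base, **overrides) if overrides else base


def _binom_weights(c: int, p: np.ndarray) -> list[np.ndarray]:
    """Binomial(c, p) pmf for b = 0..c, elementwise over p."""
    q = 1.0 - p
    return [math.comb(c, b) * p ** b * q ** (c - b) for b in range(c + 1)]


def emission_logliks(lrr: np.ndarray, baf: np.ndarray, pfb: np.ndarray,
                     params: HmmParams) -> np.ndarray:
    """Per-state emission log-likelihoods, shape (5, n_markers).

    Missing LRR/BAF values contribute a neutral 0 term; monomorphic
    probes contribute LRR only, so their state discrimination rests
    entirely on intensity.
    """
    n = len(lrr)
    out = np.zeros((5, n))
    sd = params.lrr_sd
    lrr_ok = np.isfinite(lrr)
    z = np.where(lrr_ok, lrr, 0.0)
    for s, mu in enumerate(params.lrr_means):
        ll = -0.5 * ((z - mu) / sd) ** 2 - math.log(sd * _SQRT2PI)
        out[s] = np.where(lrr_ok, ll, 0.0)

    polymorphic = (pfb >= 0.0) & (pfb <= 1.0)
    baf_ok = np.isfinite(baf) & polymorphic
    if not baf_ok.any():
        return out
    b = np.where(baf_ok, baf, 0.5)
    p = np.where(polymorphic, pfb, 0.5)
    at_lo = b <= _BOUNDARY_EPS
    at_hi = b >= 1.0 - _BOUNDARY_EPS
    interior = ~(at_lo | at_hi)
    bsd = params.baf_sd

    # state 0: uniform BAF with a small boundary atom
    like0 = np.where(interior, 1.0, _STATE0_BOUNDARY)
    out[0] += np.where(baf_ok, np.log(like0), 0.0)

    from scipy.stats import norm
    for c in range(1, 5):
        centers = np.array([bb / c for bb in range(c + 1)])
        weights = _binom_weights(c, p)
        like = np.zeros(n)
        for bb in range(c + 1):
            mu = centers[bb]
            w = weights[bb]
            dens = np.exp(-0.5 * ((b - mu) / bsd) ** 2) / (bsd * _SQRT2PI)
            mass_lo = norm.cdf((0.0 - mu) / bsd)
            mass_hi = norm.sf((1.0 - mu) / bsd)
            like += w * np.where(at_lo, mass_lo,
                                 np.where(at_hi, mass_hi, dens))
        out[c] += np.where(baf_ok,
                           np.log(np.maximum(like, _DENSITY_FLOOR)), 0.0)
    return out


def emission_loglik(lrr: float, baf: float, pfb: float, state: int,
                    params: HmmParams | None = None) -> float:
    """Scalar emission log-likelihood of one marker under one state."""
    params = params or HmmParams()
    mat = emission_logliks(np.array([lrr], float), np.array([baf], float),
                           np.array([pfb], float), params)
    return float(mat[state, 0])


def viterbi_path(emis: np.ndarray, pos: np.ndarray,
                 params: HmmParams) -> np.ndarray:
    """Most likely state path for one chromosome track.

    ``emis``: (5, n) emission log-likelihoods; ``pos``: marker bp
    positions.  The initial distribution anchors the path in the diploid
    state with leave probability ``lambda_max``.
    """
    n = emis.shape[1]
    if n == 0:
        return np.zeros(0, dtype=np.int8)
    lam0 = params.lambda_max
    log_pi = np.full(5, math.log(lam0 / 4.0))
    log_pi[2] = math.log(1.0 - lam0)
    d = np.diff(pos).astype(float)
    lam = params.lambda_max * (1.0 - np.exp(-d / params.transition_bp))
    lam = np.clip(lam, 1e-12, 0.5)
    log_stay = np.log1p(-lam)
    log_jump = np.log(lam / 4.0)

    score = log_pi + emis[:, 0]
    back = np.zeros((n, 5), dtype=np.int8)
    for j in range(1, n):
        stay = score + log_stay[j - 1]
        # best predecessor overall and runner-up, for the t != s jump
        order = np.argsort(score)
        best, second = order[-1], order[-2]
        jump_from = np.full(5, best)
        jump_from[best] = second
        jump = score[jump_from] + log_jump[j - 1]
        take_stay = stay >= jump
        back[j] = np.where(take_stay, np.arange(5), jump_from)
        score = np.where(take_stay, stay, jump) + emis[:, j]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for j in range(n - 1, 0, -1):
        path[j - 1] = back[j, path[j]]
    return path


def _runs_to_calls(path: np.ndarray, emis: np.ndarray, pos: np.ndarray,
                   sample_id: str, chrom: str,
                   params: HmmParams) -> list[dict]:
    calls = []
    n = len(path)
    j = 0
    while j < n:
        s = path[j]
        k = j
        while k < n and path[k] == s:
            k += 1
        if s != 2:
            conf = float(np.sum(emis[s, j:k] - emis[2, j:k]))
            nm = k - j
            if nm >= params.min_markers and conf >= params.min_confidence:
                calls.append({
                    "sample_id": sample_id, "chrom": chrom,
                    "start_pos": int(pos[j]), "end_pos": int(pos[k - 1]),
                    "cn": int(s), "n_markers": int(nm),
                    "length_bp": int(pos[k - 1] - pos[j] + 1),
                    "confidence": conf,
                })
        j = k
    return calls


def sample_lrr_sd(panel: IntensityPanel) -> pd.Series:
    """Robust per-sample LRR noise (scaled MAD), indexed by sample id."""
    med = np.nanmedian(panel.lrr, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(panel.lrr - med), axis=1)
    return pd.Series(1.4826 * mad, index=panel.samples)


def call_cnvs(panel: IntensityPanel, params: HmmParams | None = None,
              pfb: np.ndarray | None = None,
              marker_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Segment every sample of a panel into a CNV callset.

    ``pfb`` overrides the marker-map PFB column (same length/order);
    ``marker_mask`` restricts calling to a boolean subset of markers
    (e.g. after QC exclusions).  Samples whose robust LRR noise exceeds
    ``params.max_lrr_sd`` are skipped entirely.
    """
    params = params or HmmParams()
    markers = panel.markers
    use = np.ones(len(markers), dtype=bool)
    use &= ~markers["unstable_region"].to_numpy(bool)
    use &= ~markers["gender_linked"].to_numpy(bool)
    if marker_mask is not None:
        use &= np.asarray(marker_mask, dtype=bool)
    if not use.any():
        raise ArrayCnvError("no markers left after exclusions")
    pfb_arr = (markers["pfb"].to_numpy(float) if pfb is None
               else np.asarray(pfb, dtype=float))
    noisy: set[str] = set()
    if params.max_lrr_sd is not None:
        sds = sample_lrr_sd(panel)
        noisy = set(sds.index[sds > params.max_lrr_sd])

    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    rows: list[dict] = []
    for chrom, sl in panel.chrom_slices().items():
        sub = np.flatnonzero(use[sl]) + sl.start
        if len(sub) == 0:
            continue
        pos = pos_arr[sub]
        pfb_c = pfb_arr[sub]
        for si, sample_id in enumerate(panel.samples):
            if sample_id in noisy:
                continue
            lrr = panel.lrr[si, sub]
            baf = panel.baf[si, sub]
            if not (np.isfinite(lrr).any() or np.isfinite(baf).any()):
                continue
            emis = emission_logliks(lrr, baf, pfb_c, params)
            path = viterbi_path(emis, pos, params)
            rows.extend(_runs_to_calls(path, emis, pos, sample_id,
                                       chrom, params))
    if not rows:
        return empty_callset()
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["sample_id", "chrom", "start_pos"],
                             kind="mergesort").reset_index(drop=True)


def reciprocal_overlap(a_start: int, a_end: int,
                       b_start: int, b_end: int) -> float:
    """Overlap length divided by the longer interval (1-based inclusive)."""
    inter = min(a_end, b_end) - max(a_start, b_start) + 1
    if inter <= 0:
        return 0.0
    return inter / max(a_end - a_start + 1, b_end - b_start + 1)


def compare_callsets(a: pd.DataFrame, b: pd.DataFrame,
                     min_overlap: float = 0.5) -> dict:
    """Concordance report between two callsets on the same samples.

    Calls match when same sample, same chromosome and reciprocal overlap
    of at least ``min_overlap``.  Returns per-sample counts and mean
    lengths plus lists of unmatched calls on each side.
    """
    a = a.reset_index(drop=True)
    b = b.reset_index(drop=True)
    sa, sb = set(a["sample_id"]), set(b["sample_id"])
    if sa and sb and not (sa & sb):
        raise ArrayCnvError("callsets cover disjoint sample sets")

    matched_a = np.zeros(len(a), dtype=bool)
    matched_b = np.zeros(len(b), dtype=bool)
    b_groups: dict[tuple, list[int]] = {}
    for j, r in b.iterrows():
        b_groups.setdefault((r["sample_id"], r["chrom"]), []).append(j)
    for i, r in a.iterrows():
        for j in b_groups.get((r["sample_id"], r["chrom"]), []):
            if matched_b[j]:
                continue
            rb = b.loc[j]
            if reciprocal_overlap(r["start_pos"], r["end_pos"],
                                  rb["start_pos"], rb["end_pos"]) \
                    >= min_overlap:
                matched_a[i] = True
                matched_b[j] = True
                break

    def _per_sample(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return pd.DataFrame(columns=["n_calls", "mean_length_bp"])
        g = df.groupby("sample_id")
        return pd.DataFrame({"n_calls": g.size(),
                             "mean_length_bp": g["length_bp"].mean()})

    return {
        "n_a": len(a), "n_b": len(b),
        "n_matched": int(matched_a.sum()),
        "frac_a_matched": float(matched_a.mean()) if len(a) else 1.0,
        "frac_b_matched": float(matched_b.mean()) if len(b) else 1.0,
        "per_sample_a": _per_sample(a),
        "per_sample_b": _per_sample(b),
        "lost": a.loc[~matched_a].reset_index(drop=True),
        "gained": b.loc[~matched_b].reset_index(drop=True),
    }


def f1_against_truth(calls: pd.DataFrame, truth: pd.DataFrame,
                     min_overlap: float = 0.5,
                     min_truth_markers: int = 0,
                     truth_marker_counts: pd.Series | None = None) -> dict:
    """Precision/recall/F1 of a callset against truth intervals.

    Matching is 50% reciprocal overlap within a sample (copy-number
    direction is not scored).  ``truth_marker_counts`` (aligned to truth
    rows) allows restricting recall to truth events of a minimum span.
    """
    t = truth.reset_index(drop=True)
    if truth_marker_counts is not None and min_truth_markers > 0:
        keep = truth_marker_counts.to_numpy() >= min_truth_markers
        t = t.loc[keep].reset_index(drop=True)
    rep = compare_callsets(
        t.assign(cn=t.get("cn", 1), n_markers=1,
                 length_bp=t["end_pos"] - t["start_pos"] + 1, confidence=0.0),
        calls, min_overlap=min_overlap) if len(t) or len(calls) else None
    if rep is None:
        return {"precision": 1.0, "recall": 1.0, "f1": 1.0}
    tp = rep["n_matched"]
    recall = tp / len(t) if len(t) else 1.0
    precision = rep["frac_b_matched"] if len(calls) else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_truth": len(t), "n_calls": len(calls)}
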