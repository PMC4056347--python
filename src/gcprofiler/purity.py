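"""Tumor purity from tumor:normal depth-ratio peaks.

A tumor sample of purity P mixes tumor and stromal (diploid) cells. In a
region the tumor carries as a heterozygous deletion (one copy, "1N"), the
expected tumor:normal depth ratio is diluted to ``1 - P/2`` relative to
the diploid ("2N") ratio, so

    P = 2 * (R2n - R1n) / R2n

where R2n and R1n are the ratio-histogram peak locations of the diploid
and haploid regions. The formula is invariant to global depth rescaling.

When purity is below roughly 0.5 the 1N peak is not distinct from the 2N
peak; the fallback anchors R1n on the mean ratio over somatic deletion
regions instead (excluding deletions also seen in the matched blood, and
discarding candidate regions whose mean ratio exceeds the 2N level as
false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

MIN_RATIO_WINDOWS = 200
DEFAULT_NORMAL_DEPTH_FLOOR = 10.0
DEFAULT_PROMINENCE_FRAC = 0.10
DEFAULT_WINDOW_SIZE = 50_000


@dataclass(frozen=True)
class RatioPeakSet:
    """Smoothed-density peaks of the depth-ratio histogram."""

    peaks: tuple[tuple[float, float], ...]  # (ratio, density weight), desc by ratio
    R2n: float
    R1n: float | None

    def __post_init__(self) -> None:
        if self.R1n is not None and not self.R2n > self.R1n:
            raise ValueError("R2n must exceed R1n when both peaks present")


@dataclass
class PurityEstimate:
    P: float | None
    method: str  # peak | deletion_anchored | undetermined
    diagnostics: dict = field(default_factory=dict)


def compute_depth_ratios(tumor_windows: pd.DataFrame,
                         normal_windows: pd.DataFrame,
                         normal_depth_floor: float = DEFAULT_NORMAL_DEPTH_FLOOR,
                         ) -> tuple[pd.DataFrame, dict]:
    """Per-window tumor/normal depth ratio on aligned windows.

    Windows whose normal depth is below the floor are dropped (counted in
    the info dict); misaligned window sets raise, naming the first
    mismatching window.
    """
    if len(tumor_windows) != len(normal_windows):
        raise ValueError(
            f"window count mismatch: {len(tumor_windows)} tumor vs "
            f"{len(normal_windows)} normal")
    t = tumor_windows.reset_index(drop=True)
    n = normal_windows.reset_index(drop=True)
    for col in ("chrom", "start", "end"):
        neq = t[col].values != n[col].values
        if neq.any():
            i = int(np.argmax(neq))
            raise ValueError(
                f"windows misaligned at index {i}: tumor "
                f"{t.loc[i, 'chrom']}:{t.loc[i, 'start']}-{t.loc[i, 'end']} "
                f"vs normal {n.loc[i, 'chrom']}:{n.loc[i, 'start']}-{n.loc[i, 'end']}")
    keep = n["depth"].values >= normal_depth_floor
    out = t.loc[keep, ["chrom", "start", "end"]].copy()
    out["ratio"] = t.loc[keep, "depth"].values / n.loc[keep, "depth"].values
    info = {"n_windows": len(t), "n_dropped_low_normal": int((~keep).sum())}
    return out.reset_index(drop=True), info


def find_ratio_peaks(ratios: np.ndarray, bandwidth: str | float = "silverman",
                     prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                     grid_points: int = 512) -> RatioPeakSet:
    """Locate ratio-histogram peaks by Gaussian-kernel density.

    The highest-density peak is taken as the diploid (2N) level; the
    highest-density peak strictly below it as the haploid (1N) level.
    Unimodal densities yield R1n=None. Requires at least 200 ratios.
    """
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if len(ratios) < MIN_RATIO_WINDOWS:
        raise ValueError(
            f"need >= {MIN_RATIO_WINDOWS} ratio windows, got {len(ratios)}")
    sigma = float(ratios.std(ddof=1))
    if bandwidth == "silverman":
        # full Silverman reference rule, 0.9 * min(sigma, IQR/1.34) *
        # n^(-1/5): the IQR term keeps the bandwidth robust when minor
        # CNV modes inflate the standard deviation
        q75, q25 = np.percentile(ratios, [75, 25])
        iqr = q75 - q25
        scale = min(sigma, iqr / 1.34) if iqr > 0 else sigma
        h = 0.9 * scale * len(ratios) ** (-0.2)
    else:
        h = float(bandwidth)
    kde = gaussian_kde(ratios, bw_method=h / sigma if sigma > 0 else 1.0)
    lo, hi = 0.0, float(np.quantile(ratios, 0.999)) * 1.2
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    idx, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    if len(idx) == 0:
        idx = np.array([int(np.argmax(dens))])
    locs = grid[idx]
    weights = dens[idx]
    order = np.argsort(-locs)
    peaks = tuple((float(locs[i]), float(weights[i])) for i in order)
    i2n = int(np.argmax(weights))
    r2n = float(locs[i2n])
    lower = [(float(l), float(w)) for l, w in zip(locs, weights) if l < r2n]
    r1n = None
    if lower:
        best = max(lower, key=lambda lw: (lw[1], -lw[0]))  # ties -> lower ratio
        r1n = best[0]
    return RatioPeakSet(peaks=peaks, R2n=r2n, R1n=r1n)


def purity_from_peaks(R2n: float, R1n: float) -> PurityEstimate:
    """P = 2 (R2n - R1n) / R2n, clamped to [0, 1]."""
    if not R2n > 0:
        raise ValueError(f"R2n must be positive, got {R2n}")
    if R1n < 0:
        raise ValueError(f"R1n must be non-negative, got {R1n}")
    if R1n > R2n:
        raise ValueError(f"inverted peak assignment: R1n={R1n} > R2n={R2n}")
    p = 2.0 * (R2n - R1n) / R2n
    p = min(max(p, 0.0), 1.0)
    return PurityEstimate(P=p, method="peak",
                          diagnostics={"R2n": R2n, "R1n": R1n})


def _region_mean_ratio(ratio_windows: pd.DataFrame,
                       regions: pd.DataFrame) -> tuple[float, int]:
    vals = []
    for reg in regions.itertuples(index=False):
        sel = ratio_windows[
            (ratio_windows["chrom"] == reg.chrom)
            & (ratio_windows["end"] > reg.start)
            & (ratio_windows["start"] < reg.end)]
        vals.extend(sel["ratio"].tolist())
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def _overlaps_any(region, others: pd.DataFrame) -> bool:
    sel = others[(others["chrom"] == region.chrom)
                 & (others["end"] > region.start)
                 & (others["start"] < region.end)]
    return len(sel) > 0


def _complement_mean_ratio(ratio_windows: pd.DataFrame,
                           regions: pd.DataFrame) -> float:
    """Mean ratio over windows overlapping none of the regions."""
    keep = np.ones(len(ratio_windows), dtype=bool)
    w = ratio_windows.reset_index(drop=True)
    for reg in regions.itertuples(index=False):
        keep &= ~((w["chrom"] == reg.chrom).values
                  & (w["end"].values > reg.start)
                  & (w["start"].values < reg.end))
    if not keep.any():
        return float("nan")
    return float(w.loc[keep, "ratio"].mean())


def purity_deletion_anchored(ratio_windows: pd.DataFrame,
                             somatic_deletions: pd.DataFrame,
                             blood_deletions: pd.DataFrame | None,
                             R2n: float) -> PurityEstimate:
    """Anchor the 1N level on somatic heterozygous-deletion regions.

    Candidate regions are somatic deletions not overlapping any blood
    deletion; a candidate whose mean ratio exceeds the 2N level is
    discarded as a false positive. R1n is the mean ratio over windows in
    the surviving regions. With no surviving region the estimate is
    method='undetermined' (no exception).
    """
    if blood_deletions is None:
        blood_deletions = pd.DataFrame(columns=["chrom", "start", "end"])
    surviving = []
    n_blood_excluded = n_false_positive = 0
    for reg in somatic_deletions.itertuples(index=False):
        if _overlaps_any(reg, blood_deletions):
            n_blood_excluded += 1
            continue
        mean_r, n_win = _region_mean_ratio(
            ratio_windows, pd.DataFrame([reg._asdict()]))
        if n_win == 0:
            continue
        if mean_r > R2n:
            n_false_positive += 1
            continue
        surviving.append(reg)
    diag = {"n_candidate": len(somatic_deletions),
            "n_blood_excluded": n_blood_excluded,
            "n_false_positive": n_false_positive,
            "n_anchoring": len(surviving), "R2n": R2n}
    if not surviving:
        return PurityEstimate(P=None, method="undetermined", diagnostics=diag)
    r1n, n_win = _region_mean_ratio(
        ratio_windows, pd.DataFrame([r._asdict() for r in surviving]))
    r1n = min(r1n, R2n)
    est = purity_from_peaks(R2n, r1n)
    est.method = "deletion_anchored"
    est.diagnostics.update(diag, n_anchor_windows=n_win, R1n=r1n)
    return est


def estimate_purity(tumor_windows: pd.DataFrame,
                    normal_windows: pd.DataFrame,
                    somatic_deletions: pd.DataFrame | None = None,
                    blood_deletions: pd.DataFrame | None = None,
                    normal_depth_floor: float = DEFAULT_NORMAL_DEPTH_FLOOR,
                    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                    ) -> PurityEstimate:
    """Peak-based estimate with deletion-anchored fallback.

    Peak mode is used when a distinct 1N peak exists and implies P >= 0.5;
    otherwise (peaks not distinct, the low-purity regime) the
    deletion-anchored mode runs if somatic deletion regions are supplied,
    else the result is 'undetermined'.
    """
    ratio_windows, info = compute_depth_ratios(
        tumor_windows, normal_windows, normal_depth_floor)
    ratios = ratio_windows["ratio"].values
    # median-normalize for diagnostics only; the formula is scale-free
    med = float(np.median(ratios))
    peaks = find_ratio_peaks(ratios, prominence_frac=prominence_frac)
    est = None
    if peaks.R1n is not None:
        est = purity_from_peaks(peaks.R2n, peaks.R1n)
    if est is not None and est.P is not None and est.P >= 0.5:
        est.diagnostics.update(info, median_ratio=med,
                               peaks=[(l / med, w) for l, w in peaks.peaks])
        return est
    if somatic_deletions is not None and len(somatic_deletions) > 0:
        # anchor both levels on means: R2n = mean ratio outside the
        # candidate deletions (mean-vs-mode mixing would bias P, the
        # window-ratio distribution being right-skewed)
        r2n_mean = _complement_mean_ratio(ratio_windows, somatic_deletions)
        anchored = purity_deletion_anchored(
            ratio_windows, somatic_deletions, blood_deletions,
            r2n_mean if np.isfinite(r2n_mean) else peaks.R2n)
        anchored.diagnostics.update(info, median_ratio=med)
        if anchored.method != "undetermined":
            return anchored
    if est is not None:
        # no usable anchor; report the (possibly sub-0.5) peak estimate
        est.diagnostics.update(info, median_ratio=med, fallback="unavailable")
        return est
    return PurityEstimate(P=None, method="undetermined",
                          diagnostics={**info, "median_ratio": med,
                                       "R2n": peaks.R2n})


def purity_report(sample: str, est: PurityEstimate) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample": sample,
        "purity": est.P if est.P is not None else np.nan,
        "method": est.method,
        "R2n": est.diagnostics.get("R2n", np.nan),
        "R1n": est.diagnostics.get("R1n", np.nan),
        "n_windows": est.diagnostics.get("n_windows", 0),
    }])
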