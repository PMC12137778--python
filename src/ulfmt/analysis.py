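"""MTR maps and derived statistics.

The magnetization transfer ratio is computed voxelwise from two magnitude
images acquired with low and high RF energy deposition,

    MTR = (MT_low - MT_high) / MT_low * 100  [percent],

with a validity threshold on MT_low because the high-flip-angle image sits
close to the noise floor at ultra-low field. This module also implements the
sweep-curve diagnostics used to pick the flip-angle pair (symmetry point,
asymmetry index, exhaustive symmetric-pair search) and the reproducibility
statistics (ROI means, histograms, Bland-Altman agreement and the
bias-corrected two-scan coefficient of variation).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .image_ops import MagnitudeImage
from .signal_model import SweepCurve

__all__ = [
    "MTRResult",
    "ReproStats",
    "SymmetryReport",
    "compute_mtr_map",
    "estimate_background_sd",
    "roi_statistics",
    "mtr_histogram",
    "scan_rescan_cov",
    "COV_SMALL_SAMPLE_FACTOR",
    "bland_altman",
    "find_symmetry_point",
    "asymmetry_index",
    "choose_flip_angle_pair",
    "symmetry_report",
]

#: Small-sample bias correction for a two-measurement CoV: 1 + 1/(4 n) at n = 2.
COV_SMALL_SAMPLE_FACTOR = 1.125


@dataclass
class MTRResult:
    """MTR map in percent; invalid voxels are NaN, never silently zeroed."""

    mtr_map: np.ndarray
    valid_mask: np.ndarray
    threshold: float
    provenance: dict = dc_field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass(frozen=True)
class ReproStats:
    """Scan-rescan agreement summary for one set of ROIs."""

    mean: float
    sd: float
    cov_percent: float
    mean_difference: float
    bias: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class SymmetryReport:
    symmetry_point: float
    asymmetry: dict[float, float]
    chosen_pair: tuple[float, float] | None = None


def _as_array(img) -> np.ndarray:
    return img.data if isinstance(img, MagnitudeImage) else np.asarray(img, dtype=float)


def estimate_background_sd(img, corner_fraction: float = 0.15) -> float:
    """Noise level estimate from the eight corner patches of a volume.

    Uses the standard deviation of intensities in corner boxes spanning
    ``corner_fraction`` of each axis, assuming the object sits centrally.
    """
    data = _as_array(img)
    n = [max(1, int(round(corner_fraction * s))) for s in data.shape]
    sls = [(slice(0, ni), slice(-ni, None)) for ni in n]
    patches = [
        data[sx, sy, sz].ravel() for sx in sls[0] for sy in sls[1] for sz in sls[2]
    ]
    return float(np.std(np.concatenate(patches)))


def compute_mtr_map(
    low,
    high,
    threshold: float | None = None,
    k_sigma: float = 5.0,
    provenance: dict | None = None,
) -> MTRResult:
    """Voxelwise MTR = (low - high) / low x 100 with an MT_low validity threshold.

    If ``threshold`` is None it defaults to ``k_sigma`` times a background
    noise estimate of the low image (the high-RF-energy image is often near
    the noise floor, so voxels with unreliable MT_low are flagged invalid
    rather than producing wild ratios). Values are not clipped: noise-driven
    negative MTR is retained so that histograms reflect the raw statistic.
    """
    low_a, high_a = _as_array(low), _as_array(high)
    if low_a.shape != high_a.shape:
        raise ValueError(f"shape mismatch: {low_a.shape} vs {high_a.shape}")
    if threshold is None:
        threshold = k_sigma * estimate_background_sd(low_a)
    valid = low_a > threshold
    if not np.any(valid):
        raise ValueError("no voxel exceeds the MT_low validity threshold")
    mtr = np.full(low_a.shape, np.nan)
    mtr[valid] = (low_a[valid] - high_a[valid]) / low_a[valid] * 100.0
    return MTRResult(mtr, valid, float(threshold), provenance or {})


def roi_statistics(result: MTRResult, labels: np.ndarray) -> pd.DataFrame:
    """Per-label mean, sample SD (n-1) and valid-voxel count.

    Empty ROIs (no valid voxel) are reported with NaN statistics and a zero
    count — an explicit missing entry rather than a silent zero.
    """
    labels = np.asarray(labels)
    if labels.shape != result.mtr_map.shape:
        raise ValueError("label map shape must match the MTR map")
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = (labels == lab) & result.valid_mask
        vals = result.mtr_map[sel]
        n = vals.size
        rows.append(
            {
                "label": int(lab),
                "mean": float(np.mean(vals)) if n else np.nan,
                "sd": float(np.std(vals, ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
                "n_voxels": n,
            }
        )
    return pd.DataFrame(rows, columns=["label", "mean", "sd", "n_voxels"])


def mtr_histogram(
    result: MTRResult,
    mask: np.ndarray | None = None,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Histogram of valid (masked) MTR values with bins anchored at zero.

    Bin edges are integer multiples of ``bin_width`` covering the data, so
    counts always sum to the number of valid masked voxels regardless of the
    bin width chosen.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    sel = result.valid_mask if mask is None else (result.valid_mask & np.asarray(mask, bool))
    vals = result.mtr_map[sel]
    if vals.size == 0:
        raise ValueError("mask selects no valid voxels")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def scan_rescan_cov(
    values_scan: Sequence[float] | float,
    values_rescan: Sequence[float] | float,
) -> np.ndarray | float:
    """Bias-corrected two-scan coefficient of variation, percent, per ROI.

    CoV = SD(scan, rescan) / mean(scan, rescan) x 1.125 x 100, where the SD
    is the two-value sample standard deviation (n-1 denominator) and the
    1.125 = 1 + 1/(4 n) factor corrects the downward bias of the CoV when it
    is estimated from only n = 2 measurements.
    """
    a = np.asarray(values_scan, dtype=float)
    b = np.asarray(values_rescan, dtype=float)
    if a.shape != b.shape:
        raise ValueError("scan and rescan value arrays must have the same shape")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("scan/rescan values must be finite")
    mean = (a + b) / 2.0
    if np.any(mean == 0):
        raise ValueError("scan-rescan mean of zero; CoV undefined")
    sd = np.abs(a - b) / np.sqrt(2.0)  # two-value sample SD
    cov = sd / mean * COV_SMALL_SAMPLE_FACTOR * 100.0
    return float(cov) if cov.ndim == 0 else cov


def bland_altman(pairs: Sequence[tuple[float, float]]) -> dict[str, float]:
    """Bland-Altman bias and 95% limits of agreement for paired measurements.

    bias = mean(scan - rescan); limits = bias +/- 1.96 x SD(differences).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (scan, rescan) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd_diff": sd,
        "mean_values": np.mean(arr, axis=1).tolist(),
        "differences": diffs.tolist(),
    }


# ---------------------------------------------------------------------------
# Sweep-curve diagnostics and pair selection
# ---------------------------------------------------------------------------


def _mirror_pairs(x: np.ndarray, axis: float, tol: float = 1e-6):
    """Indices (i, j) of grid points mirror-symmetric about ``axis``, x[i] < axis < x[j]."""
    pairs = []
    values = {round(float(v), 9): k for k, v in enumerate(x)}
    for i, xi in enumerate(x):
        if xi >= axis:
            break
        partner = 2.0 * axis - xi
        j = values.get(round(float(partner), 9))
        if j is None:
            # tolerate floating-point grids
            close = np.nonzero(np.abs(x - partner) <= tol)[0]
            j = int(close[0]) if close.size else None
        if j is not None:
            pairs.append((i, int(j)))
    return pairs


def find_symmetry_point(curve: SweepCurve) -> float:
    """Grid flip angle about which the sweep curve is most mirror-symmetric.

    For every candidate axis on the curve's grid the mean absolute
    difference |S(a - d) - S(a + d)| over all offsets d with both mirror
    points on the grid is scored; the axis with the smallest score wins,
    ties going to the smaller angle. Candidates with no mirror pair at all
    (grid edges) are skipped. The curve must span at least (10, 350) degrees.
    """
    x, s = curve.x_values, curve.signals
    if x.min() > 10.0 or x.max() < 350.0:
        raise ValueError("sweep must span at least 10 to 350 degrees")
    candidates = []  # (score, n_pairs, axis)
    for axis in x:
        pairs = _mirror_pairs(x, float(axis))
        if not pairs:
            continue
        score = float(np.mean([abs(s[i] - s[j]) for i, j in pairs]))
        candidates.append((score, len(pairs), float(axis)))
    if not candidates:
        raise ValueError("no candidate axis with mirror pairs on this grid")
    # A rotation by alpha equals one by alpha - 360, so a sweep extending past
    # 360 degrees is exactly symmetric about 360 as well; among axes tied at
    # (numerically) zero asymmetry prefer the one supported by the most
    # mirror pairs, then the smaller angle.
    smin = min(c[0] for c in candidates)
    zero_tol = 1e-9 * float(np.max(np.abs(s)))
    tied = [c for c in candidates if c[0] <= smin + zero_tol]
    tied.sort(key=lambda c: (-c[1], c[2]))
    return tied[0][2]


def asymmetry_index(curve: SweepCurve, symmetry_point: float, delta: float) -> float:
    """Normalized signal asymmetry [S(a*-d) - S(a*+d)] / [S(a*-d) + S(a*+d)].

    Positive values mean more signal on the low-flip-angle side, the
    signature of bound-pool saturation growing with RF energy.
    """
    x, s = curve.x_values, curve.signals
    lo, hi = symmetry_point - delta, symmetry_point + delta
    i = np.nonzero(np.abs(x - lo) <= 1e-6)[0]
    j = np.nonzero(np.abs(x - hi) <= 1e-6)[0]
    if i.size == 0 or j.size == 0:
        raise ValueError(f"both {lo} and {hi} degrees must lie on the sweep grid")
    a, b = s[int(i[0])], s[int(j[0])]
    if a + b == 0:
        raise ValueError("zero denominator in asymmetry index")
    return float((a - b) / (a + b))


def choose_flip_angle_pair(
    curve_no_mt: SweepCurve,
    curve_mt: SweepCurve,
    signal_match_tol: float = 0.05,
    min_signal_frac: float = 0.9,
) -> tuple[float, float]:
    """Select the (low, high) flip-angle pair for differential MT imaging.

    Among pairs mirror-symmetric about the no-MT curve's symmetry point,
    keep those whose no-MT signals match within ``signal_match_tol`` of the
    curve maximum (equal non-MT weighting) and whose signal is at least
    ``min_signal_frac`` of the maximum (stay near the signal peak); among
    the feasible pairs return the one maximizing the predicted MTR on the MT
    curve. Ties prefer higher no-MT signal, then the smaller low angle.
    """
    if not 0 < signal_match_tol <= 1 or not 0 < min_signal_frac <= 1:
        raise ValueError("tolerances must lie in (0, 1]")
    if not np.array_equal(curve_no_mt.x_values, curve_mt.x_values):
        raise ValueError("both curves must share the same flip-angle grid")
    x = curve_no_mt.x_values
    s_ref = curve_no_mt.signals
    s_mt = curve_mt.signals
    axis = find_symmetry_point(curve_no_mt)
    s_max = float(s_ref.max())

    best = None  # (mtr, s_low_ref, -alpha_low, pair)
    for i, j in _mirror_pairs(x, axis):
        if abs(s_ref[i] - s_ref[j]) / s_max > signal_match_tol:
            continue
        if s_ref[i] < min_signal_frac * s_max:
            continue
        if s_mt[i] <= 0:
            continue
        mtr = (s_mt[i] - s_mt[j]) / s_mt[i] * 100.0
        key = (mtr, s_ref[i], -x[i])
        if best is None or key > best[0]:
            best = (key, (float(x[i]), float(x[j])))
    if best is None:
        raise ValueError("no feasible symmetric flip-angle pair under the given tolerances")
    return best[1]


def symmetry_report(
    curve_no_mt: SweepCurve,
    curve_mt: SweepCurve | None = None,
    deltas: Sequence[float] = (60.0, 120.0),
) -> SymmetryReport:
    """Symmetry point, asymmetry indices and (optionally) the chosen pair."""
    sp = find_symmetry_point(curve_no_mt)
    target = curve_mt if curve_mt is not None else curve_no_mt
    asym = {}
    for d in deltas:
        try:
            asym[float(d)] = asymmetry_index(target, sp, float(d))
        except ValueError:
            continue
    pair = None
    if curve_mt is not None:
        try:
            pair = choose_flip_angle_pair(curve_no_mt, curve_mt)
        except ValueError:
            pair = None
    return SymmetryReport(symmetry_point=sp, asymmetry=asym, chosen_pair=pair)
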