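"""Line-profile signal-to-noise estimation and paired filter comparison.

The SNR statistic follows the line-profile protocol: gray values are read
along a segment crossing a fluorescent object, each sample is allocated to
signal or background, and

    SNR = delta_mu / sigma = (mean(signal) - mean(background)) / s.d.(background).

The paired bandpass-vs-longpass comparison uses the two-sided Wilcoxon
signed-rank test; the exact null distribution is enumerated (dynamic
programming over signed ranks, ties handled by mid-ranks) for effective
n <= 25, with the tie-corrected normal approximation above that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special
from scipy.stats import rankdata
from skimage.filters import threshold_otsu

from .frames import FieldImage

__all__ = [
    "LineProfile",
    "SNRResult",
    "PairedComparison",
    "AllocationError",
    "extract_profile",
    "allocate_profile",
    "compute_snr",
    "wilcoxon_signed_rank",
    "compare_filters",
]

EXACT_N_MAX = 25


class AllocationError(ValueError):
    """Profile cannot be split into signal and background (no contrast)."""


@dataclass
class LineProfile:
    """Ordered gray-value samples along a transect, optionally labeled.

    ``labels`` entries are ``"signal"``, ``"background"`` or ``""`` (unset).
    """

    positions: np.ndarray
    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not self.labels:
            self.labels = [""] * len(self.values)
        if len(self.labels) != len(self.values):
            raise ValueError("labels must match values in length")

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        sig = self.values[[l == "signal" for l in self.labels]]
        bg = self.values[[l == "background" for l in self.labels]]
        return sig, bg


@dataclass
class SNRResult:
    delta_mu: float
    sigma_bg: float
    snr: float
    n_signal: int
    n_background: int


@dataclass
class PairedComparison:
    pairs: list[tuple[float, float]]
    median_bp: float
    median_lp: float
    statistic: float  # W+ = rank sum of positive differences
    p_value: float
    n_pairs: int
    n_effective: int  # pairs remaining after dropping zero differences
    degenerate: bool = False
    method: str = "exact"


def extract_profile(
    image: FieldImage, p0: tuple[float, float], p1: tuple[float, float]
) -> LineProfile:
    """Sample gray values along a segment at unit-pixel spacing.

    Endpoints are ``(row, col)`` pixel coordinates, both inclusive; values
    are bilinearly interpolated, giving ``round(length) + 1`` samples.
    """
    r0, c0 = p0
    r1, c1 = p1
    h, w = image.shape
    for r, c in (p0, p1):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(f"endpoint ({r}, {c}) lies outside the image")
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0:
        raise ValueError("zero-length segment")
    n = int(round(length)) + 1
    t = np.linspace(0.0, 1.0, n)
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    values = ndimage.map_coordinates(
        image.pixels.astype(np.float64), [rows, cols], order=1, mode="nearest"
    )
    return LineProfile(positions=np.arange(n, dtype=float), values=values)


def allocate_profile(
    profile: LineProfile,
    method: str = "otsu",
    manual_labels: list[str] | None = None,
) -> LineProfile:
    """Label each sample as signal or background.

    ``otsu`` thresholds the value distribution (samples >= threshold become
    signal); ``manual`` applies caller-provided labels verbatim, which is
    the first-class route for curated profiles.
    """
    if method == "manual":
        if manual_labels is None:
            raise ValueError("manual allocation requires manual_labels")
        if len(manual_labels) != len(profile.values):
            raise ValueError("manual_labels length mismatch")
        return LineProfile(profile.positions.copy(), profile.values.copy(), list(manual_labels))
    if method != "otsu":
        raise ValueError(f"unknown allocation method {method!r}")
    if len(profile.values) < 4:
        raise AllocationError("otsu allocation needs at least 4 samples")
    if np.ptp(profile.values) == 0:
        raise AllocationError("constant profile has no contrast to allocate")
    thr = threshold_otsu(profile.values)
    labels = ["signal" if v > thr else "background" for v in profile.values]
    if "signal" not in labels or "background" not in labels:
        raise AllocationError("otsu allocation produced a single class")
    return LineProfile(profile.positions.copy(), profile.values.copy(), labels)


def compute_snr(profile: LineProfile, ddof: int = 1) -> SNRResult:
    """SNR = (mean signal - mean background) / s.d.(background).

    The background s.d. uses the sample (n-1) form by default; ``ddof=0``
    switches to the population form.
    """
    sig, bg = profile.split()
    if len(sig) < 1:
        raise ValueError("profile has no signal samples")
    if len(bg) < 2:
        raise ValueError("profile needs at least 2 background samples")
    sigma = float(np.std(bg, ddof=ddof))
    if sigma == 0:
        raise ValueError("degenerate background: zero standard deviation")
    delta_mu = float(np.mean(sig) - np.mean(bg))
    return SNRResult(
        delta_mu=delta_mu,
        sigma_bg=sigma,
        snr=delta_mu / sigma,
        n_signal=len(sig),
        n_background=len(bg),
    )


def _exact_signed_rank_tail(ranks: np.ndarray, w_plus: float) -> float:
    """One-sided exact p for the signed-rank statistic via DP enumeration.

    Enumerates the null distribution of W+ over all 2^n sign assignments by
    convolving the per-rank {0, r} contributions.  Mid-ranks from ties are
    half-integers, so all ranks are doubled to work on an integer lattice.
    Returns the smaller tail probability P(W+ >= w) or P(W+ <= w).
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(np.rint(2 * w_plus))
    upper = float(dist[w2:].sum())
    lower = float(dist[: w2 + 1].sum())
    return min(upper, lower)


def wilcoxon_signed_rank(differences: np.ndarray) -> tuple[float, float, bool, str]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (signed-rank convention).  Returns
    ``(W_plus, p_value, degenerate, method)``; an all-zero input is reported
    as degenerate with W = 0 and p = 1.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, True, "degenerate"
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        p = min(1.0, 2.0 * _exact_signed_rank_tail(ranks, w_plus))
        return w_plus, p, False, "exact"
    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return w_plus, 1.0, True, "degenerate"
    z = (w_plus - mean) / np.sqrt(var)
    p = min(1.0, float(special.erfc(abs(z) / np.sqrt(2.0))))
    return w_plus, p, False, "normal"


def compare_filters(pairs: list[tuple[float, float]]) -> PairedComparison:
    """Paired BP-vs-LP SNR comparison (two-sided Wilcoxon signed-rank)."""
    if len(pairs) < 1:
        raise ValueError("need at least one complete pair")
    bp = np.array([p[0] for p in pairs], dtype=np.float64)
    lp = np.array([p[1] for p in pairs], dtype=np.float64)
    w, p, degenerate, method = wilcoxon_signed_rank(bp - lp)
    return PairedComparison(
        pairs=list(pairs),
        median_bp=float(np.median(bp)),
        median_lp=float(np.median(lp)),
        statistic=w,
        p_value=p,
        n_pairs=len(pairs),
        n_effective=int(np.count_nonzero(bp - lp)),
        degenerate=degenerate,
        method=method,
    )
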