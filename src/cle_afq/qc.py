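"""Automated frame exclusion: no-signal, motion-artifact and duplicate flags.

The study protocol this mirrors excluded frames with no discernible signal,
obvious motion artifacts, and repeats of an identical or very similar field
of view.  The original exclusion was visual; here each rule gets an explicit
quantitative surrogate calibrated on synthetic frames:

* ``no_signal`` — too few pixels rise above a robust (median/MAD) background
  band of ``k_sigma`` robust s.d.;
* ``motion`` — a directional smear makes the local gradient field strongly
  anisotropic everywhere; the flag thresholds the *median over a tile grid*
  of structure-tensor eigenvalue ratios, which keeps sensitivity to global
  smear while ignoring legitimately oriented anatomy (a single fiber);
* ``duplicate`` — high normalized cross-correlation (after 8x downsampling,
  over shifts up to 10% of the field of view) against an earlier kept frame
  of the same case.

Precedence is total: no_signal > motion > duplicate; an excluded frame
carries exactly the first flag that fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.feature import match_template
from skimage.measure import block_reduce

from .frames import FieldImage, robust_background
from .cohort import reconcile_percentages

__all__ = [
    "QCThresholds",
    "QCReport",
    "flag_no_signal",
    "motion_anisotropy",
    "flag_motion",
    "flag_duplicates",
    "qc_pipeline",
]


@dataclass
class QCThresholds:
    """Config-file values, not constants; defaults calibrated on synthetic frames."""

    k_sigma: float = 4.0
    min_frac: float = 1e-4
    anisotropy_threshold: float = 1.6
    ncc_threshold: float = 0.95

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QCThresholds":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def flag_no_signal(image: FieldImage, k_sigma: float = 4.0, min_frac: float = 1e-4) -> bool:
    """True iff too few pixels exceed robust background + ``k_sigma`` robust s.d.

    A constant frame (MAD = 0 and nothing above the median) counts as
    signal-free rather than raising.
    """
    med, sd = robust_background(image.pixels)
    if sd == 0:
        # perfectly flat frame: nothing discernible by construction
        return True
    frac = float(np.mean(image.pixels.astype(np.float64) > med + k_sigma * sd))
    return frac < min_frac


def motion_anisotropy(image: FieldImage, tiles: tuple[int, int] = (6, 6)) -> float:
    """Median over tiles of the structure-tensor eigenvalue ratio.

    Gradients are taken on a lightly smoothed frame; each tile contributes
    the ratio of the largest to smallest eigenvalue of its mean gradient
    outer-product.  Isotropic content gives ratios near 1; a global smear
    suppresses the gradient component along the motion direction in every
    tile and drives the median up.
    """
    g = ndimage.gaussian_filter(image.pixels.astype(np.float64), 1.5)
    gy, gx = np.gradient(g)
    h, w = g.shape
    th, tw = h // tiles[0], w // tiles[1]
    ratios = []
    for i in range(tiles[0]):
        for j in range(tiles[1]):
            sl = (slice(i * th, (i + 1) * th), slice(j * tw, (j + 1) * tw))
            jxx = float(np.mean(gx[sl] ** 2))
            jyy = float(np.mean(gy[sl] ** 2))
            jxy = float(np.mean(gx[sl] * gy[sl]))
            tr2 = 0.5 * (jxx + jyy)
            disc = np.sqrt(max(0.25 * (jxx - jyy) ** 2 + jxy**2, 0.0))
            lo = tr2 - disc
            ratios.append((tr2 + disc) / lo if lo > 0 else np.inf)
    return float(np.median(ratios))


def flag_motion(image: FieldImage, anisotropy_threshold: float = 1.6) -> bool:
    return motion_anisotropy(image) > anisotropy_threshold


def _downsample(image: FieldImage) -> np.ndarray:
    # pre-smoothing suppresses per-pixel noise so the correlation reflects
    # shared scene content rather than independent noise realizations
    g = ndimage.gaussian_filter(image.pixels.astype(np.float64), 8.0)
    return block_reduce(g, (8, 8), np.mean)


def duplicate_ncc(a_ds: np.ndarray, b_ds: np.ndarray, max_shift_frac: float = 0.10) -> float:
    """Max normalized cross-correlation over shifts up to a FOV fraction."""
    dr = max(1, int(round(a_ds.shape[0] * max_shift_frac)))
    dc = max(1, int(round(a_ds.shape[1] * max_shift_frac)))
    template = a_ds[dr:-dr, dc:-dc]
    score = match_template(b_ds, template)
    return float(score.max())


def flag_duplicates(
    images: list[FieldImage], ncc_threshold: float = 0.95
) -> dict[str, tuple[str | None, float]]:
    """Duplicate assignment within one case, in acquisition (input) order.

    Returns ``{image_id: (duplicate_of | None, best_ncc)}``.  A frame is
    compared against every *earlier non-duplicate* frame of the same case,
    so the duplicate_of graph always points backwards and is acyclic.
    """
    out: dict[str, tuple[str | None, float]] = {}
    kept: list[tuple[str, np.ndarray]] = []
    for img in images:
        ds = _downsample(img)
        best_id, best = None, -np.inf
        for prev_id, prev_ds in kept:
            score = duplicate_ncc(prev_ds, ds)
            if score > best:
                best_id, best = prev_id, score
        if best_id is not None and best >= ncc_threshold:
            out[img.image_id] = (best_id, best)
        else:
            out[img.image_id] = (None, best if kept else 0.0)
            kept.append((img.image_id, ds))
    return out


@dataclass
class QCReport:
    """Per-image exclusion decisions plus cohort tallies.

    ``pct`` holds integer percentages per category reconciled to sum to 100
    (largest-remainder rounding).  Categories with no defined criterion in
    this implementation (blood contamination, out-of-focus areas) are listed
    under ``unsupported_categories`` rather than silently dropped.
    """

    records: list[dict] = field(default_factory=list)
    tally: dict[str, int] = field(default_factory=dict)
    pct: dict[str, int] = field(default_factory=dict)
    unsupported_categories: tuple[str, ...] = ("blood_contamination", "out_of_focus")

    @property
    def kept_ids(self) -> list[str]:
        return [r["image_id"] for r in self.records if r["decision"] == "kept"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_json(self) -> dict:
        return {
            "records": self.records,
            "tally": self.tally,
            "pct": self.pct,
            "unsupported_categories": list(self.unsupported_categories),
        }


def qc_pipeline(
    images: list[FieldImage], thresholds: QCThresholds | None = None
) -> QCReport:
    """Apply the exclusion flags with precedence no_signal > motion > duplicate.

    Duplicate comparison runs per case among frames that survived the first
    two flags, in input (acquisition) order.
    """
    th = thresholds or QCThresholds()
    report = QCReport()
    if not images:
        report.tally = {"no_signal": 0, "motion": 0, "duplicate": 0, "kept": 0}
        report.pct = {}
        return report

    survivors: dict[str, list[FieldImage]] = {}
    decisions: dict[str, dict] = {}
    for img in images:
        rec = {
            "image_id": img.image_id,
            "case_id": img.case_id,
            "no_signal": False,
            "motion": False,
            "duplicate_of": None,
        }
        if flag_no_signal(img, th.k_sigma, th.min_frac):
            rec.update(no_signal=True, decision="excluded", reason="no_signal")
        elif flag_motion(img, th.anisotropy_threshold):
            rec.update(motion=True, decision="excluded", reason="motion")
        else:
            rec.update(decision="kept", reason="")
            survivors.setdefault(img.case_id, []).append(img)
        decisions[img.image_id] = rec

    for case_imgs in survivors.values():
        dup = flag_duplicates(case_imgs, th.ncc_threshold)
        for image_id, (dup_of, _score) in dup.items():
            if dup_of is not None:
                decisions[image_id].update(
                    duplicate_of=dup_of, decision="excluded", reason="duplicate"
                )

    report.records = [decisions[img.image_id] for img in images]
    tally = {"no_signal": 0, "motion": 0, "duplicate": 0, "kept": 0}
    for rec in report.records:
        tally[rec["reason"] if rec["decision"] == "excluded" else "kept"] += 1
    report.tally = tally
    labels = list(tally)
    pct = reconcile_percentages([tally[k] for k in labels])
    report.pct = dict(zip(labels, pct))
    return report
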