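"""Synthetic-cohort study routines shared by the test suite and scripts.

Each function generates its own frames through :mod:`cle_afq.simulate`,
runs the relevant part of the pipeline, and reports summary statistics.
Randomized scene specifications draw object counts with a margin to the
sparse/dense classification boundaries (49/50 spots, 4/5 cells) so that a
±1-2 counting error cannot change the ground-truth flag a frame carries.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .detect import DetectorParams, FeatureVector, analyze_frame, classify_features, detect_spots
from .frames import PIXEL_SIZE_UM
from .qc import QCThresholds, qc_pipeline
from .simulate import GroundTruth, SceneSpec, inject_artifact, render_pair, render_scene
from .snr import LineProfile, compare_filters, compute_snr, extract_profile

__all__ = [
    "random_scene_spec",
    "ground_truth_features",
    "match_detections",
    "spot_recovery",
    "detection_benchmark",
    "qc_benchmark",
    "paired_filter_study",
    "snr_consistency",
    "signed_rank_enumeration_p",
]


def random_scene_spec(rng: np.random.Generator, seed: int) -> SceneSpec:
    """Randomized per-frame scene at default contrast.

    Counts are drawn away from the classification boundaries: spots from
    {0} ∪ [1, 45] ∪ [55, 110], cells from {0..3} ∪ {6..9}.
    """
    u = rng.random()
    if u < 0.2:
        n_spots = 0
    elif u < 0.6:
        n_spots = int(rng.integers(1, 46))
    else:
        n_spots = int(rng.integers(55, 111))

    def cell_count(p_zero=0.35, p_sparse=0.40):
        v = rng.random()
        if v < p_zero:
            return 0
        if v < p_zero + p_sparse:
            return int(rng.integers(1, 4))
        return int(rng.integers(6, 10))

    return SceneSpec(
        n_spots=n_spots,
        n_small_cells=cell_count(),
        n_large_cells=cell_count(0.5, 0.35),
        n_fibers=int(rng.integers(0, 3)),
        n_round=int(rng.integers(0, 4)),
        diffuse_level=float(rng.uniform(85, 115)) if rng.random() < 0.3 else 0.0,
        seed=seed,
    )


def ground_truth_features(gt: GroundTruth) -> FeatureVector:
    """The feature vector implied by the planted annotations."""
    counts = gt.counts()
    fake = []
    for cls, n in counts.items():
        fake.extend([_FakeDet(cls)] * n)
    return classify_features(fake, (gt.diffuse, 1.0 if gt.diffuse else 0.0))


class _FakeDet:
    __slots__ = ("cls",)

    def __init__(self, cls: str):
        self.cls = cls


def match_detections(detections, gt: GroundTruth, cls: str, tol_um: float = 1.0):
    """Greedy centroid matching; returns (true positives, n_det, n_truth)."""
    truths = gt.of_class(cls)
    dets = [d for d in detections if d.cls == cls]
    used: set[int] = set()
    tp = 0
    for d in dets:
        best, best_dist = None, tol_um
        for i, o in enumerate(truths):
            if i in used:
                continue
            dist = float(np.hypot(d.x_um - o.x_um, d.y_um - o.y_um))
            if dist <= best_dist:
                best, best_dist = i, dist
        if best is not None:
            used.add(best)
            tp += 1
    return tp, len(dets), len(truths)


def spot_recovery(
    n_frames: int = 10,
    seed: int = 0,
    contrast: float = 8.0,
    diameter_um: float = 2.0,
    params: DetectorParams | None = None,
) -> dict:
    """Recall/precision of spot detection on frames of 30 planted spots."""
    tp = nd = ng = 0
    for i in range(n_frames):
        spec = SceneSpec(
            n_spots=30,
            spot_diameter_um=(diameter_um, diameter_um),
            object_contrast=contrast,
            seed=seed + i,
        )
        img, gt = render_scene(spec, "BP", seed=seed + i)
        dets = detect_spots(img, params)
        t, d, g = match_detections(dets, gt, "spot", tol_um=1.0)
        tp, nd, ng = tp + t, nd + d, ng + g
    return {
        "recall": tp / ng if ng else 0.0,
        "precision": tp / nd if nd else 1.0,
        "n_frames": n_frames,
    }


def detection_benchmark(
    n_frames: int = 100, seed: int = 0, params: DetectorParams | None = None
) -> dict:
    """Nine-flag agreement between detected and planted feature vectors.

    Returns the fraction of (frame, flag) cells in agreement overall and
    restricted to the two punctuate flags.
    """
    from .cohort import FEATURES

    rng = np.random.default_rng(seed)
    punct = ("sparse_punctuate", "dense_punctuate")
    agree = {f: 0 for f in FEATURES}
    for i in range(n_frames):
        spec = random_scene_spec(rng, seed=seed * 100003 + i)
        img, gt = render_scene(spec, "BP", seed=spec.seed)
        _, fv = analyze_frame(img, params)
        expected = ground_truth_features(gt)
        for f in FEATURES:
            if getattr(fv, f) == getattr(expected, f):
                agree[f] += 1
    total_cells = n_frames * len(FEATURES)
    return {
        "flag_agreement": sum(agree.values()) / total_cells,
        "punctuate_agreement": sum(agree[f] for f in punct) / (n_frames * len(punct)),
        "per_flag": {f: agree[f] / n_frames for f in FEATURES},
        "n_frames": n_frames,
    }


def qc_benchmark(
    n_frames: int = 300, seed: int = 0, thresholds: QCThresholds | None = None
) -> dict:
    """Sensitivity/specificity of the QC flags on a labeled synthetic set.

    Frames are organized in cases of ten; each case holds clean frames plus
    injected blank, motion (50 px smear) and duplicate (<= 10 px shift)
    artifacts at known positions.
    """
    rng = np.random.default_rng(seed)
    images, truth = [], []
    n_cases = max(1, n_frames // 10)
    idx = 0
    for c in range(n_cases):
        case_id = f"case{c:03d}"
        prev_clean = None
        for j in range(10):
            if idx >= n_frames:
                break
            s = seed * 100003 + idx
            spec = SceneSpec(
                n_spots=int(rng.integers(15, 40)),
                n_small_cells=int(rng.integers(1, 5)),
                n_fibers=int(rng.integers(0, 2)),
                n_round=int(rng.integers(0, 3)),
                seed=s,
            )
            img, _ = render_scene(spec, "BP", seed=s, case_id=case_id, image_id=f"im{idx:04d}")
            u = rng.random()
            if u < 0.15:
                img = inject_artifact(img, "blank", seed=s)
                label = "no_signal"
            elif u < 0.30:
                img = inject_artifact(img, "motion", 50, seed=s)
                label = "motion"
            elif u < 0.45 and prev_clean is not None:
                img = inject_artifact(prev_clean, "duplicate", 10, seed=s)
                label = "duplicate"
            else:
                label = "kept"
                prev_clean = img
            img = type(img)(
                pixels=img.pixels, pixel_size_um=img.pixel_size_um, filter=img.filter,
                case_id=case_id, image_id=f"im{idx:04d}", acquisition=img.acquisition,
                meta=img.meta,
            )
            images.append(img)
            truth.append(label)
            idx += 1
    report = qc_pipeline(images, thresholds)
    predicted = [
        rec["reason"] if rec["decision"] == "excluded" else "kept" for rec in report.records
    ]
    out: dict = {"n_frames": len(images), "tally": report.tally}
    for kind in ("no_signal", "motion", "duplicate"):
        tp = sum(1 for t, p in zip(truth, predicted) if t == kind and p == kind)
        fn = sum(1 for t, p in zip(truth, predicted) if t == kind and p != kind)
        fp = sum(1 for t, p in zip(truth, predicted) if t != kind and p == kind)
        tn = sum(1 for t, p in zip(truth, predicted) if t != kind and p != kind)
        out[kind] = {
            "sensitivity": tp / (tp + fn) if tp + fn else 1.0,
            "specificity": tn / (tn + fp) if tn + fp else 1.0,
            "n_positive": tp + fn,
        }
    return out


def _pair_profile_snr(seed: int, contrast: float) -> tuple[float, float]:
    """SNR of the same planted object in matched BP/LP frames.

    One 3 µm spot per field; a 60 px transect crosses it, with geometric
    labels (core <= 2 px -> signal, beyond 10 px -> background).
    """
    spec = SceneSpec(
        n_spots=1, spot_diameter_um=(3.0, 3.0), object_contrast=contrast, seed=seed
    )
    bp, lp, gt = render_pair(spec, seed=seed)
    o = gt.of_class("spot")[0]
    row, col = o.y_um / PIXEL_SIZE_UM, o.x_um / PIXEL_SIZE_UM
    c0, c1 = max(col - 30, 0.0), min(col + 30, bp.shape[1] - 1.0)
    out = []
    for img in (bp, lp):
        prof = extract_profile(img, (row, c0), (row, c1))
        labels = []
        for t in prof.positions:
            dt = abs((c0 + t) - col)
            labels.append("signal" if dt <= 2 else ("background" if dt >= 10 else ""))
        labeled = LineProfile(prof.positions, prof.values, labels)
        out.append(compute_snr(labeled).snr)
    return out[0], out[1]


def paired_filter_study(
    n_pairs: int = 50, n_cohorts: int = 20, seed: int = 0, contrast: float = 3.0
) -> dict:
    """Matched BP/LP cohorts differing only in background offset.

    Signal amplitude is identical in both filters, so the SNR difference
    should be indistinguishable from zero: the study reports the pooled
    median difference and the fraction of cohorts whose two-sided Wilcoxon
    test retains the null at the 5% level.
    """
    diffs, retained, cohort_stats = [], 0, []
    for c in range(n_cohorts):
        pairs = [
            _pair_profile_snr(seed * 1000003 + c * 1009 + i, contrast)
            for i in range(n_pairs)
        ]
        res = compare_filters(pairs)
        d = [a - b for a, b in pairs]
        diffs.extend(d)
        if res.p_value > 0.05:
            retained += 1
        cohort_stats.append({"median_diff": float(np.median(d)), "p": res.p_value})
    return {
        "median_diff": float(np.median(diffs)),
        "null_retention_frac": retained / n_cohorts,
        "n_pairs": n_pairs,
        "n_cohorts": n_cohorts,
        "cohorts": cohort_stats,
    }


def snr_consistency(
    n_profiles: int = 500,
    n_background: int = 200,
    n_signal: int = 20,
    true_snr: float = 5.0,
    seed: int = 0,
) -> dict:
    """Mean absolute error of the SNR estimator on Gaussian profiles.

    Background N(mu, sigma^2), signal N(mu + true_snr * sigma, sigma^2),
    labels known; reports mean |SNR_hat - true| / true.
    """
    rng = np.random.default_rng(seed)
    mu, sigma = 100.0, 10.0
    errors = []
    for _ in range(n_profiles):
        bg = rng.normal(mu, sigma, n_background)
        sig = rng.normal(mu + true_snr * sigma, sigma, n_signal)
        values = np.concatenate([bg, sig])
        labels = ["background"] * n_background + ["signal"] * n_signal
        prof = LineProfile(np.arange(len(values), dtype=float), values, labels)
        errors.append(abs(compute_snr(prof).snr - true_snr))
    return {
        "mean_abs_error": float(np.mean(errors)),
        "relative_error": float(np.mean(errors)) / true_snr,
        "n_profiles": n_profiles,
        "n_background": n_background,
    }


def signed_rank_enumeration_p(differences: np.ndarray) -> tuple[float, float]:
    """Brute-force signed-rank reference: enumerate all 2^n sign patterns.

    Independent of the production implementation; only usable for small n.
    Returns (W_plus, two-sided p by doubling the smaller tail, capped at 1).
    """
    from scipy.stats import rankdata

    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    if n > 16:
        raise ValueError("enumeration reference is for small n only")
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = [sum(r for r, s in zip(ranks, signs) if s) for signs in product([False, True], repeat=n)]
    ws = np.asarray(ws, dtype=float)
    upper = np.mean(ws >= w_obs)
    lower = np.mean(ws <= w_obs)
    return w_obs, min(1.0, 2.0 * min(upper, lower))
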