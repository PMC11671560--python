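"""Per-case aggregation, cohort tallies and Chernoff-face glyph encoding.

A case's feature abundance is the percentage of its analyzable frames in
which each of the nine autofluorescence features was detected.  Each case is
then drawn as a Chernoff face: nine facial parameters in [0, 1] carry the
nine abundances (pct / 100) under a fixed slot assignment, and every other
facial parameter stays at its default of 0.5.  The face geometry itself is
an original, documented parameterization; only the feature-to-slot mapping
is fixed by the scoring scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from matplotlib.backends.backend_svg import FigureCanvasSVG
from matplotlib.figure import Figure

__all__ = [
    "FEATURES",
    "GLYPH_SLOTS",
    "CaseSummary",
    "GlyphSpec",
    "round_half_away",
    "reconcile_percentages",
    "situ_category_summary",
    "aggregate_case",
    "glyph_spec",
    "render_glyph",
    "cohort_report",
]

#: canonical order of the nine scored autofluorescence features
FEATURES = (
    "sparse_punctuate",
    "dense_punctuate",
    "sparse_small_cells",
    "dense_small_cells",
    "sparse_large_cells",
    "dense_large_cells",
    "diffuse",
    "fibers",
    "round_structures",
)

#: fixed face-parameter slot per feature in the nine-feature scoring scheme
GLYPH_SLOTS = {
    "face_size": "sparse_punctuate",
    "forehead_jaw_arc": "diffuse",
    "forehead_shape": "fibers",
    "jaw_shape": "dense_punctuate",
    "eye_angle": "round_structures",
    "pupil_direction": "sparse_small_cells",
    "nose_length": "dense_large_cells",
    "mouth_shape": "dense_small_cells",
    "mouth_arc": "sparse_large_cells",
}

UNMAPPED_DEFAULT = 0.5


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconcile_percentages(counts: list[int]) -> list[int]:
    """Integer percentages of ``counts`` summing exactly to 100.

    Each share is first rounded to the nearest integer (half away from
    zero); any discrepancy from 100 is then settled on the entries with the
    largest (for a deficit) or smallest (for a surplus) fractional
    remainders, ties broken by input order.
    """
    total = sum(counts)
    if total == 0:
        return [0] * len(counts)
    raw = [100.0 * c / total for c in counts]
    pct = [round_half_away(r) for r in raw]
    frac = [r - math.floor(r) for r in raw]
    delta = 100 - sum(pct)
    order = sorted(range(len(counts)), key=lambda i: (-frac[i], i))
    i = 0
    while delta > 0 and len(counts) > 0:
        pct[order[i % len(order)]] += 1
        delta -= 1
        i += 1
    order_desc = sorted(range(len(counts)), key=lambda i: (frac[i], i))
    i = 0
    while delta < 0:
        j = order_desc[i % len(order_desc)]
        if pct[j] > 0:
            pct[j] -= 1
            delta += 1
        i += 1
    return pct


def situ_category_summary(total: int, category_counts: list[int]) -> dict:
    """Percentage per exclusion/analysis category plus the remainder count.

    Percentages are plain nearest-integer (half away from zero) shares of
    ``total``, matching how cohort tallies are conventionally reported; the
    remainder is ``total - sum(category_counts)`` (frames not in any listed
    category).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if any(c < 0 for c in category_counts):
        raise ValueError("category counts must be >= 0")
    if sum(category_counts) > total:
        raise ValueError("category counts exceed the total")
    pct = [round_half_away(100.0 * c / total) for c in category_counts]
    return {
        "total": int(total),
        "counts": [int(c) for c in category_counts],
        "percentages": pct,
        "remainder": int(total - sum(category_counts)),
    }


@dataclass
class CaseSummary:
    """Per-case abundance: percentage of analyzable frames showing each feature."""

    case_id: str
    tumor_type: str = ""
    n_images: int = 0
    pct: dict[str, float] = field(default_factory=dict)


def aggregate_case(feature_rows: pd.DataFrame, tumor_type: str = "") -> CaseSummary:
    """Aggregate per-frame feature flags of one case into abundances.

    ``feature_rows`` must hold one row per analyzable frame with boolean
    columns named after :data:`FEATURES` and a single ``case_id``.  Frames
    excluded by QC must be filtered out before calling this.
    """
    if len(feature_rows) == 0:
        raise ValueError("zero analyzable frames for this case")
    case_ids = set(feature_rows["case_id"].astype(str))
    if len(case_ids) != 1:
        raise ValueError(f"rows span multiple cases: {sorted(case_ids)}")
    n = len(feature_rows)
    pct = {
        f: 100.0 * float(np.asarray(feature_rows[f], dtype=bool).sum()) / n
        for f in FEATURES
    }
    return CaseSummary(case_id=case_ids.pop(), tumor_type=tumor_type, n_images=n, pct=pct)


@dataclass
class GlyphSpec:
    """Nine mapped face parameters in [0, 1]; everything else sits at 0.5."""

    face_size: float = UNMAPPED_DEFAULT
    forehead_jaw_arc: float = UNMAPPED_DEFAULT
    forehead_shape: float = UNMAPPED_DEFAULT
    jaw_shape: float = UNMAPPED_DEFAULT
    eye_angle: float = UNMAPPED_DEFAULT
    pupil_direction: float = UNMAPPED_DEFAULT
    nose_length: float = UNMAPPED_DEFAULT
    mouth_shape: float = UNMAPPED_DEFAULT
    mouth_arc: float = UNMAPPED_DEFAULT
    #: parameters of the face model that carry no data
    unmapped_default: float = UNMAPPED_DEFAULT
    #: source abundances (percent) kept alongside so the pct -> spec -> pct
    #: round trip is exact, free of the 1-ulp drift of /100 followed by *100
    source_pct: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for slot in GLYPH_SLOTS:
            v = getattr(self, slot)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{slot} must lie in [0, 1], got {v}")

    def to_pct(self) -> dict[str, float]:
        """Invert the encoding: the feature abundances in percent."""
        if self.source_pct is not None:
            return dict(self.source_pct)
        return {feat: 100.0 * getattr(self, slot) for slot, feat in GLYPH_SLOTS.items()}


def glyph_spec(summary: CaseSummary) -> GlyphSpec:
    """Encode a case's abundances: parameter = pct / 100, componentwise."""
    kwargs = {slot: summary.pct[feat] / 100.0 for slot, feat in GLYPH_SLOTS.items()}
    return GlyphSpec(**kwargs, source_pct={f: summary.pct[f] for f in FEATURES})


def _draw_face(ax, spec: GlyphSpec) -> None:
    """Documented geometric construction of the face.

    All coordinates live in [-1, 1]^2.  ``face_size`` scales the whole face
    (0.55 + 0.45 p); the outline is two half-ellipses (forehead above, jaw
    below) joined at an equator whose height is set by ``forehead_jaw_arc``,
    which shifts arc length between forehead and jaw.  Eyes are ellipses
    rotated by ``eye_angle``; pupils slide horizontally with
    ``pupil_direction``; the nose is a vertical segment of length
    ``nose_length``; the mouth is a parabola whose half-width follows
    ``mouth_arc`` and whose curvature follows ``mouth_shape``.
    """
    s = 0.55 + 0.45 * spec.face_size
    half_w = 0.75 * s
    y_eq = (spec.forehead_jaw_arc - 0.5) * 0.5 * s
    forehead_h = (0.5 + 0.5 * spec.forehead_shape) * s
    jaw_h = (0.5 + 0.5 * spec.jaw_shape) * s

    t = np.linspace(0.0, math.pi, 80)
    ax.plot(half_w * np.cos(t), y_eq + forehead_h * np.sin(t), color="k", lw=1.2)
    ax.plot(half_w * np.cos(t), y_eq - jaw_h * np.sin(t), color="k", lw=1.2)

    eye_y = y_eq + 0.45 * forehead_h
    eye_dx = 0.38 * half_w
    angle = (spec.eye_angle - 0.5) * 60.0
    for sign in (-1.0, 1.0):
        cx = sign * eye_dx
        a = math.radians(sign * angle)
        u = np.linspace(0, 2 * math.pi, 60)
        ex, ey = 0.16 * s * np.cos(u), 0.08 * s * np.sin(u)
        ax.plot(
            cx + ex * math.cos(a) - ey * math.sin(a),
            eye_y + ex * math.sin(a) + ey * math.cos(a),
            color="k", lw=1.0,
        )
        px = cx + (spec.pupil_direction - 0.5) * 0.16 * s
        ax.plot([px], [eye_y], marker="o", markersize=2.5, color="k")

    nose_len = (0.1 + 0.35 * spec.nose_length) * s
    ax.plot([0, 0], [y_eq + 0.1 * s, y_eq + 0.1 * s - nose_len], color="k", lw=1.2)

    mouth_y = y_eq - 0.55 * jaw_h
    mouth_hw = (0.12 + 0.3 * spec.mouth_arc) * half_w
    curv = (spec.mouth_shape - 0.5) * 0.5 * s
    mx = np.linspace(-mouth_hw, mouth_hw, 40)
    my = mouth_y + curv * (1.0 - (mx / max(mouth_hw, 1e-9)) ** 2)
    ax.plot(mx, my, color="k", lw=1.2)

    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")


def _deterministic_save(fig: Figure, out_path: Path) -> None:
    with matplotlib.rc_context({"svg.hashsalt": "cle-afq"}):
        FigureCanvasSVG(fig)
        fig.savefig(out_path, format="svg", metadata={"Date": None})


def render_glyph(spec: GlyphSpec, out_path: str | Path, title: str = "") -> Path:
    """Draw one face as SVG; identical specs give byte-identical output."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig = Figure(figsize=(2.2, 2.4))
    ax = fig.add_axes([0.02, 0.02, 0.96, 0.88])
    _draw_face(ax, spec)
    if title:
        ax.set_title(title, fontsize=9)
    _deterministic_save(fig, out_path)
    return out_path


def render_glyph_grid(summaries: list[CaseSummary], out_path: str | Path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    n = len(summaries)
    ncols = min(6, max(1, n))
    nrows = int(math.ceil(n / ncols))
    fig = Figure(figsize=(2.0 * ncols, 2.2 * nrows))
    for i, summary in enumerate(summaries):
        ax = fig.add_subplot(nrows, ncols, i + 1)
        _draw_face(ax, glyph_spec(summary))
        label = summary.case_id
        if summary.tumor_type:
            label += f"\n{summary.tumor_type}"
        ax.set_title(label, fontsize=8)
    _deterministic_save(fig, out_path)
    return out_path


def cohort_report(summaries: list[CaseSummary], outdir: str | Path) -> dict[str, Path]:
    """Write the per-case abundance table, glyph grid and per-type medians."""
    if not summaries:
        raise ValueError("need at least one case summary")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for s in summaries:
        row = {"case_id": s.case_id, "tumor_type": s.tumor_type, "n_images": s.n_images}
        row.update({f: s.pct[f] for f in FEATURES})
        rows.append(row)
    summary_df = pd.DataFrame(rows)
    summary_path = outdir / "summary.csv"
    summary_df.to_csv(summary_path, index=False)

    grid_path = render_glyph_grid(summaries, outdir / "glyphs.svg")

    medians = (
        summary_df.groupby("tumor_type")[list(FEATURES)].median().reset_index()
        if summary_df["tumor_type"].any()
        else pd.DataFrame(columns=["tumor_type", *FEATURES])
    )
    medians_path = outdir / "per_type_median_pct.csv"
    medians.to_csv(medians_path, index=False)
    return {"summary": summary_path, "glyphs": grid_path, "medians": medians_path}
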