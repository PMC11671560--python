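"""Synthetic label-free CLE autofluorescence frame generator.

Real label-free endomicroscopy recordings of brain tissue are not publicly
deposited, so this module emulates their image formation well enough to
exercise the full analysis chain with known ground truth:

* punctuate autofluorescence: bright 2-D Gaussian spots, 1-3 µm FWHM;
* cells with fluorescent cytoplasm: disks with a darker nucleus and a
  granular (textured) cytoplasmic annulus, small (<25 µm) or large (>=25 µm);
* autofluorescent fibers: smoothed random-walk polylines of given width;
* round structures (psammoma-body-like): weak, homogeneous disks 10-60 µm;
* diffuse autofluorescence: a low-spatial-frequency field covering the
  field of view, carrying a few negative-contrast silhouettes;
* filter-dependent background: LP frames add a constant offset to the
  BP background level before noise;
* Poisson photon noise (variance = poisson_scale x mean) plus Gaussian
  read noise, and optional motion / blank / duplicate artifacts.

All randomness flows from one root seed through fixed per-purpose
substreams, so adding objects of one class never perturbs another class,
and a given (spec, filter, seed) renders bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .frames import DTYPE_MAX, FOV_UM, IMAGE_SHAPE, PIXEL_SIZE_UM, FieldImage, robust_background

__all__ = [
    "NoiseParams",
    "SceneSpec",
    "GroundTruthObject",
    "GroundTruth",
    "PackingError",
    "render_scene",
    "render_pair",
    "inject_artifact",
]

# fixed substream keys: one per object class / purpose, so that changing the
# count of one class leaves every other class's draws untouched
_STREAMS = {
    "spots": 1,
    "small_cells": 2,
    "large_cells": 3,
    "fibers": 4,
    "round": 5,
    "diffuse": 6,
    "noise_BP": 10,
    "noise_LP": 11,
    "artifact": 12,
}

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # Gaussian FWHM / sigma

ARTIFACT_KINDS = ("motion", "blank", "duplicate")


class PackingError(RuntimeError):
    """Requested objects cannot be placed in the field of view."""


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[name])))


@dataclass
class NoiseParams:
    """Poisson-Gaussian sensor model.

    ``poisson_scale`` is the gray-value gain per detected photon: a frame of
    mean ``m`` carries shot-noise variance ``poisson_scale * m``.
    ``read_sigma`` is the additive Gaussian read-noise s.d. in gray units.
    Either may be zero (zero -> that component is switched off), which gives
    noiseless renders for geometric ground-truth checks.

    The defaults put the sensor in a read-noise-dominated regime: the
    background s.d. then barely changes with the background level, which is
    the regime in which matched bandpass/longpass acquisitions of the same
    scene show no systematic SNR difference despite the brighter longpass
    background.
    """

    poisson_scale: float = 0.1
    read_sigma: float = 30.0


@dataclass
class SceneSpec:
    """Generator configuration for one synthetic field of view.

    Object contrasts are expressed in units of the BP background noise s.d.
    ``sigma_ref = sqrt(poisson_scale * bp_background + read_sigma**2)``, so the
    same spec keeps its detectability when the noise model changes.
    """

    n_spots: int = 0
    spot_diameter_um: tuple[float, float] = (1.0, 3.0)
    n_small_cells: int = 0
    small_cell_diameter_um: tuple[float, float] = (8.0, 22.0)
    n_large_cells: int = 0
    large_cell_diameter_um: tuple[float, float] = (25.0, 40.0)
    n_fibers: int = 0
    fiber_length_um: tuple[float, float] = (60.0, 150.0)
    fiber_width_um: tuple[float, float] = (1.5, 3.5)
    n_round: int = 0
    round_diameter_um: tuple[float, float] = (15.0, 50.0)
    diffuse_level: float = 0.0
    bp_background: float = 500.0
    lp_background_offset: float = 200.0
    object_contrast: float = 8.0
    round_contrast: float = 3.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    #: target frame mean as a fraction of the 16-bit range when autobrightness
    #: emulation is enabled; None leaves absolute gray levels untouched
    autobrightness_target: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.noise, dict):
            self.noise = NoiseParams(**self.noise)
        self.validate()

    def validate(self) -> None:
        for name in ("n_spots", "n_small_cells", "n_large_cells", "n_fibers", "n_round"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.spot_diameter_um
        if not (1.0 <= lo <= hi <= 3.0):
            raise ValueError("spot diameters must lie within [1, 3] µm")
        lo, hi = self.small_cell_diameter_um
        if not (3.0 < lo <= hi < 25.0):
            raise ValueError("small-cell diameters must lie within (3, 25) µm")
        lo, hi = self.large_cell_diameter_um
        if not (25.0 <= lo <= hi):
            raise ValueError("large-cell diameters must be >= 25 µm")
        lo, hi = self.round_diameter_um
        if not (10.0 <= lo <= hi <= 60.0):
            raise ValueError("round-structure diameters must lie within [10, 60] µm")
        if self.lp_background_offset < 0:
            raise ValueError("lp_background_offset must be >= 0")
        if self.noise.poisson_scale < 0 or self.noise.read_sigma < 0:
            raise ValueError("noise parameters must be >= 0")
        self._check_footprint()

    def _check_footprint(self) -> None:
        area = 0.0
        area += self.n_spots * math.pi * (self.spot_diameter_um[1] / 2) ** 2
        area += self.n_small_cells * math.pi * (self.small_cell_diameter_um[1] / 2) ** 2
        area += self.n_large_cells * math.pi * (self.large_cell_diameter_um[1] / 2) ** 2
        area += self.n_round * math.pi * (self.round_diameter_um[1] / 2) ** 2
        area += self.n_fibers * self.fiber_length_um[1] * self.fiber_width_um[1]
        fov_area = FOV_UM[0] * FOV_UM[1]
        if area > fov_area:
            raise PackingError(
                f"total object footprint {area:.0f} µm² exceeds the FOV area {fov_area:.0f} µm²"
            )

    @property
    def sigma_ref(self) -> float:
        """Background noise s.d. of a BP frame, the contrast unit.

        When noise is fully disabled (noiseless geometry renders) the unit
        falls back to the default sensor model, so objects keep the same
        absolute amplitude they would have at default noise.
        """
        var = self.noise.poisson_scale * self.bp_background + self.noise.read_sigma**2
        if var == 0:
            default = NoiseParams()
            var = default.poisson_scale * self.bp_background + default.read_sigma**2
        return math.sqrt(var)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        for key in (
            "spot_diameter_um",
            "small_cell_diameter_um",
            "large_cell_diameter_um",
            "fiber_length_um",
            "fiber_width_um",
            "round_diameter_um",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruthObject:
    """One planted object: class, position (µm, pixel-center origin), size, peak."""

    cls: str
    x_um: float
    y_um: float
    equivalent_diameter_um: float | None = None
    length_um: float | None = None
    width_um: float | None = None
    peak: float = 0.0


@dataclass
class GroundTruth:
    objects: list[GroundTruthObject] = field(default_factory=list)
    diffuse: bool = False
    artifact: str = "none"
    seed: int = 0

    def of_class(self, cls: str) -> list[GroundTruthObject]:
        return [o for o in self.objects if o.cls == cls]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for o in self.objects:
            out[o.cls] = out.get(o.cls, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "objects": [asdict(o) for o in self.objects],
            "diffuse": self.diffuse,
            "artifact": self.artifact,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            objects=[GroundTruthObject(**o) for o in d.get("objects", [])],
            diffuse=bool(d.get("diffuse", False)),
            artifact=d.get("artifact", "none"),
            seed=int(d.get("seed", 0)),
        )


# ----------------------------------------------------------------------------
# scene construction (noise-free signal canvas + annotations)
# ----------------------------------------------------------------------------


def _place_center(rng: np.random.Generator, margin_px: float) -> tuple[float, float]:
    h, w = IMAGE_SHAPE
    row = rng.uniform(margin_px, h - 1 - margin_px)
    col = rng.uniform(margin_px, w - 1 - margin_px)
    return row, col


def _add_gaussian_spot(canvas, row, col, diameter_px, amplitude):
    sigma = diameter_px / _FWHM
    r = max(2, int(math.ceil(4 * sigma)))
    r0, r1 = int(row) - r, int(row) + r + 1
    c0, c1 = int(col) - r, int(col) + r + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, canvas.shape[0]), min(c1, canvas.shape[1])
    rows = np.arange(r0c, r1c)[:, None] - row
    cols = np.arange(c0c, c1c)[None, :] - col
    canvas[r0c:r1c, c0c:c1c] += amplitude * np.exp(
        -(rows**2 + cols**2) / (2 * sigma**2)
    )


def _dist_grid(row, col, radius_px, pad, shape):
    r = int(math.ceil(radius_px + pad))
    r0, c0 = max(int(row) - r, 0), max(int(col) - r, 0)
    r1, c1 = min(int(row) + r + 1, shape[0]), min(int(col) + r + 1, shape[1])
    rows = np.arange(r0, r1)[:, None] - row
    cols = np.arange(c0, c1)[None, :] - col
    return (slice(r0, r1), slice(c0, c1)), np.hypot(rows, cols)


def _add_cell(canvas, rng, row, col, diameter_px, amplitude):
    """Disk with darker nucleus and granular cytoplasmic annulus."""
    radius = diameter_px / 2.0
    sl, dist = _dist_grid(row, col, radius, 4, canvas.shape)
    base = np.where(dist < 0.45 * radius, 0.25, 1.0)
    g = rng.standard_normal(dist.shape)
    g = ndimage.gaussian_filter(g, 2.0)
    s = g.std()
    if s > 0:
        g = g / s
    texture = np.clip(1.0 + 0.3 * g, 0.55, 1.45)
    # edge window with half-maximum exactly at the nominal radius
    edge = np.clip((radius - dist) / 1.5 + 0.5, 0.0, 1.0)
    canvas[sl] += amplitude * base * texture * edge


def _add_disk(canvas, row, col, diameter_px, amplitude):
    """Homogeneous disk with a 1-2 px soft edge (round structures)."""
    radius = diameter_px / 2.0
    sl, dist = _dist_grid(row, col, radius, 4, canvas.shape)
    edge = np.clip((radius - dist) / 1.5 + 0.5, 0.0, 1.0)
    canvas[sl] += amplitude * edge


def _fiber_path(rng, length_px, margin_px=8.0):
    """Smoothed random-walk polyline, reflected off the frame borders."""
    h, w = IMAGE_SHAPE
    step = 3.0
    n_steps = max(2, int(round(length_px / step)))
    row, col = _place_center(rng, 40)
    theta = rng.uniform(0, 2 * math.pi)
    pts = [(row, col)]
    for _ in range(n_steps):
        theta += rng.normal(0.0, 0.18)
        row += step * math.sin(theta)
        col += step * math.cos(theta)
        if row < margin_px or row > h - 1 - margin_px:
            theta = -theta
            row = min(max(row, margin_px), h - 1 - margin_px)
        if col < margin_px or col > w - 1 - margin_px:
            theta = math.pi - theta
            col = min(max(col, margin_px), w - 1 - margin_px)
        pts.append((row, col))
    return np.asarray(pts)


def _add_fiber(canvas, path, width_px, amplitude):
    rows, cols = path[:, 0], path[:, 1]
    pad = int(math.ceil(width_px / 2 + 4))
    r0 = max(int(rows.min()) - pad, 0)
    r1 = min(int(rows.max()) + pad + 1, canvas.shape[0])
    c0 = max(int(cols.min()) - pad, 0)
    c1 = min(int(cols.max()) + pad + 1, canvas.shape[1])
    mask = np.ones((r1 - r0, c1 - c0), dtype=bool)
    # densely interpolate the polyline and stamp the centerline
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    n_dense = int(seg_len.sum() * 2) + 2
    t = np.linspace(0, 1, n_dense)
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    if cum[-1] == 0:
        return
    dense_r = np.interp(t * cum[-1], cum, rows)
    dense_c = np.interp(t * cum[-1], cum, cols)
    ir = np.clip(np.round(dense_r).astype(int) - r0, 0, mask.shape[0] - 1)
    ic = np.clip(np.round(dense_c).astype(int) - c0, 0, mask.shape[1] - 1)
    mask[ir, ic] = False
    dist = ndimage.distance_transform_edt(mask)
    half = width_px / 2.0
    profile = np.clip((half - dist) / 1.5 + 0.5, 0.0, 1.0)
    canvas[r0:r1, c0:c1] += amplitude * profile


def _diffuse_field(rng, level):
    """Smooth random field in [0.5, 1] x level, with negative-contrast disks."""
    coarse = rng.standard_normal((135, 240))
    coarse = ndimage.gaussian_filter(coarse, 20.0, mode="reflect")
    coarse -= coarse.min()
    if coarse.max() > 0:
        coarse /= coarse.max()
    fld = resize(coarse, IMAGE_SHAPE, order=1, anti_aliasing=False, preserve_range=True)
    fld = level * (0.5 + 0.5 * fld)
    # a few weakly fluorescent silhouettes appearing as negative contrast
    for _ in range(3):
        d_um = rng.uniform(30.0, 60.0)
        radius = d_um / 2.0 / PIXEL_SIZE_UM
        row, col = _place_center(rng, radius + 2)
        sl, dist = _dist_grid(row, col, radius, 4, fld.shape)
        inside = np.clip((radius - dist) / 2.0 + 0.5, 0.0, 1.0)
        fld[sl] *= 1.0 - 0.7 * inside
    return fld


def build_scene(spec: SceneSpec, seed: int | None = None):
    """Construct the noise-free object canvas, diffuse field and annotations.

    Returns ``(signal, diffuse_field, GroundTruth)`` where ``signal`` holds
    object intensities above background (gray units) and ``diffuse_field``
    the diffuse autofluorescence component (zeros when disabled).
    """
    if seed is None:
        seed = spec.seed
    canvas = np.zeros(IMAGE_SHAPE, dtype=np.float64)
    amp = spec.object_contrast * spec.sigma_ref
    amp_round = spec.round_contrast * spec.sigma_ref
    gt = GroundTruth(seed=int(seed), diffuse=spec.diffuse_level > 0)

    # round structures first: fibers must not cross them
    rng = _stream(seed, "round")
    round_geo: list[tuple[float, float, float]] = []
    for _ in range(spec.n_round):
        d_um = rng.uniform(*spec.round_diameter_um)
        radius_px = d_um / 2.0 / PIXEL_SIZE_UM
        row, col = _place_center(rng, radius_px + 2)
        _add_disk(canvas, row, col, d_um / PIXEL_SIZE_UM, amp_round)
        round_geo.append((row, col, radius_px))
        gt.objects.append(
            GroundTruthObject(
                "round", col * PIXEL_SIZE_UM, row * PIXEL_SIZE_UM,
                equivalent_diameter_um=d_um, peak=amp_round,
            )
        )

    for cls, n, rng_name, drange in (
        ("small_cell", spec.n_small_cells, "small_cells", spec.small_cell_diameter_um),
        ("large_cell", spec.n_large_cells, "large_cells", spec.large_cell_diameter_um),
    ):
        rng = _stream(seed, rng_name)
        for _ in range(n):
            d_um = rng.uniform(*drange)
            radius_px = d_um / 2.0 / PIXEL_SIZE_UM
            row, col = _place_center(rng, radius_px + 2)
            _add_cell(canvas, rng, row, col, d_um / PIXEL_SIZE_UM, amp)
            gt.objects.append(
                GroundTruthObject(
                    cls, col * PIXEL_SIZE_UM, row * PIXEL_SIZE_UM,
                    equivalent_diameter_um=d_um, peak=amp,
                )
            )

    rng = _stream(seed, "fibers")
    for _ in range(spec.n_fibers):
        length_um = rng.uniform(*spec.fiber_length_um)
        width_um = rng.uniform(*spec.fiber_width_um)
        width_px = width_um / PIXEL_SIZE_UM
        path = None
        for _attempt in range(1000):
            cand = _fiber_path(rng, length_um / PIXEL_SIZE_UM)
            ok = True
            for row, col, radius_px in round_geo:
                dmin = np.hypot(cand[:, 0] - row, cand[:, 1] - col).min()
                if dmin < radius_px + width_px:
                    ok = False
                    break
            if ok:
                path = cand
                break
        if path is None:
            raise PackingError("could not place a fiber clear of round structures")
        _add_fiber(canvas, path, width_px, amp)
        seg = np.diff(path, axis=0)
        true_len = float(np.hypot(seg[:, 0], seg[:, 1]).sum()) * PIXEL_SIZE_UM
        mid = path[len(path) // 2]
        gt.objects.append(
            GroundTruthObject(
                "fiber", mid[1] * PIXEL_SIZE_UM, mid[0] * PIXEL_SIZE_UM,
                length_um=true_len, width_um=width_um, peak=amp,
            )
        )

    rng = _stream(seed, "spots")
    for _ in range(spec.n_spots):
        d_um = rng.uniform(*spec.spot_diameter_um)
        radius_px = d_um / 2.0 / PIXEL_SIZE_UM
        row, col = _place_center(rng, radius_px + 4)
        _add_gaussian_spot(canvas, row, col, d_um / PIXEL_SIZE_UM, amp)
        gt.objects.append(
            GroundTruthObject(
                "spot", col * PIXEL_SIZE_UM, row * PIXEL_SIZE_UM,
                equivalent_diameter_um=d_um, peak=amp,
            )
        )

    if spec.diffuse_level > 0:
        diffuse = _diffuse_field(_stream(seed, "diffuse"), spec.diffuse_level)
    else:
        diffuse = np.zeros(IMAGE_SHAPE, dtype=np.float64)
    return canvas, diffuse, gt


def _apply_noise(mean: np.ndarray, noise: NoiseParams, rng: np.random.Generator):
    out = mean
    if noise.poisson_scale > 0:
        out = noise.poisson_scale * rng.poisson(
            np.maximum(mean, 0.0) / noise.poisson_scale
        ).astype(np.float64)
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=mean.shape)
    return out


def _finalize(mean: np.ndarray, spec: SceneSpec, noise_rng: np.random.Generator):
    if spec.autobrightness_target is not None:
        target = spec.autobrightness_target * DTYPE_MAX
        m = mean.mean()
        if m > 0:
            mean = mean * (target / m)
    out = _apply_noise(mean, spec.noise, noise_rng)
    return np.clip(np.rint(out), 0, DTYPE_MAX).astype(np.uint16)


def render_scene(
    spec: SceneSpec,
    filter: str = "BP",
    seed: int | None = None,
    case_id: str = "",
    image_id: str = "",
    acquisition: str = "ex_vivo",
) -> tuple[FieldImage, GroundTruth]:
    """Render one frame and its ground-truth annotations.

    LP frames add ``spec.lp_background_offset`` to the background level
    before noise; object amplitudes are identical for both filters.
    """
    if seed is None:
        seed = spec.seed
    signal, diffuse, gt = build_scene(spec, seed)
    background = spec.bp_background + (
        spec.lp_background_offset if filter == "LP" else 0.0
    )
    mean = background + diffuse + signal
    pixels = _finalize(mean, spec, _stream(seed, f"noise_{filter}"))
    img = FieldImage(
        pixels=pixels,
        filter=filter,
        case_id=case_id,
        image_id=image_id or f"sim-{seed}-{filter}",
        acquisition=acquisition,
        meta={"seed": int(seed), "artifact": "none"},
    )
    return img, gt


def render_pair(
    spec: SceneSpec, seed: int | None = None, case_id: str = ""
) -> tuple[FieldImage, FieldImage, GroundTruth]:
    """Render matched BP/LP frames of the same field of view.

    Object placement is shared; only the background level and the noise
    realizations differ (independent noise substreams per filter).
    """
    if seed is None:
        seed = spec.seed
    signal, diffuse, gt = build_scene(spec, seed)
    out = []
    for filt in ("BP", "LP"):
        background = spec.bp_background + (
            spec.lp_background_offset if filt == "LP" else 0.0
        )
        pixels = _finalize(background + diffuse + signal, spec, _stream(seed, f"noise_{filt}"))
        out.append(
            FieldImage(
                pixels=pixels,
                filter=filt,
                case_id=case_id,
                image_id=f"sim-{seed}-{filt}",
                acquisition="ex_vivo",
                meta={"seed": int(seed), "artifact": "none"},
            )
        )
    return out[0], out[1], gt


def inject_artifact(
    image: FieldImage, kind: str, strength: float = 50.0, seed: int = 0
) -> FieldImage:
    """Degrade a frame with one of the acquisition artifacts seen in situ.

    ``motion``: directional smear by a line kernel of ``strength`` px at a
    random orientation, plus a light dose of fresh read noise.  ``blank``:
    background + noise only (robust background statistics of the input).
    ``duplicate``: sub-pixel shifted copy (shift magnitude <= ``strength``
    px per axis) with fresh read noise, recording the source image id.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; expected one of {ARTIFACT_KINDS}")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS["artifact"])))
    med, sd = robust_background(image.pixels)
    pixels = image.pixels.astype(np.float64)

    if kind == "blank":
        out = med + rng.normal(0.0, max(sd, 1.0), size=pixels.shape)
        meta = {"artifact": "blank"}
    elif kind == "motion":
        if strength <= 0:
            raise ValueError("motion strength (smear length in px) must be > 0")
        length = max(2, int(round(strength)))
        theta = rng.uniform(0, math.pi)
        t = np.arange(length) - (length - 1) / 2.0
        rows = np.rint(t * math.sin(theta)).astype(int)
        cols = np.rint(t * math.cos(theta)).astype(int)
        half = length // 2 + 1
        kernel = np.zeros((2 * half + 1, 2 * half + 1))
        kernel[rows + half, cols + half] += 1.0
        kernel /= kernel.sum()
        out = ndimage.convolve(pixels, kernel, mode="nearest")
        out = out + rng.normal(0.0, 0.15 * max(sd, 1.0), size=pixels.shape)
        meta = {"artifact": "motion", "smear_px": length}
    else:  # duplicate
        shift = rng.uniform(-strength, strength, size=2)
        out = ndimage.shift(pixels, shift, order=1, mode="nearest")
        out = out + rng.normal(0.0, 0.3 * max(sd, 1.0), size=pixels.shape)
        meta = {"artifact": "duplicate", "duplicate_of": image.image_id,
                "shift_px": [float(shift[0]), float(shift[1])]}

    out = np.clip(np.rint(out), 0, DTYPE_MAX).astype(np.uint16)
    new_meta = dict(image.meta)
    new_meta.update(meta)
    return FieldImage(
        pixels=out,
        pixel_size_um=image.pixel_size_um,
        filter=image.filter,
        case_id=image.case_id,
        image_id=f"{image.image_id}-{kind}",
        acquisition=image.acquisition,
        meta=new_meta,
    )
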