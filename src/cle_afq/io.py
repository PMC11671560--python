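"""Frame I/O: 16-bit single-channel TIFF plus a JSON metadata sidecar.

Each frame ``X.tiff`` may carry a sidecar ``X.json`` holding the acquisition
metadata and, for synthetic frames, the generator configuration and
ground-truth annotations.  The sidecar schema is versioned so downstream
readers can evolve.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .frames import DimensionError, FieldImage, IMAGE_SHAPE, PIXEL_SIZE_UM
from .simulate import GroundTruth, SceneSpec

SIDECAR_SCHEMA_VERSION = 1


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_field_image(
    image: FieldImage,
    path: str | Path,
    scene_spec: SceneSpec | None = None,
    ground_truth: GroundTruth | None = None,
) -> Path:
    """Write a frame as 16-bit grayscale TIFF with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.pixels.astype(np.uint16))
    sidecar = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "pixel_size_um": image.pixel_size_um,
        "filter": image.filter,
        "case_id": image.case_id,
        "image_id": image.image_id,
        "acquisition": image.acquisition,
        "meta": image.meta,
    }
    if scene_spec is not None:
        sidecar["scene_spec"] = scene_spec.to_dict()
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth.to_dict()
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_field_image(
    path: str | Path,
    allow_any_size: bool = False,
    **defaults,
) -> FieldImage:
    """Read a TIFF frame; metadata from the sidecar or keyword defaults.

    Raises :class:`DimensionError` for multi-channel input, and for frames
    that are not 1080 x 1920 unless ``allow_any_size`` is set (in which case
    the sidecar/default ``pixel_size_um`` is taken at face value).
    """
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim != 2:
        raise DimensionError(
            f"{path.name}: expected a single-channel grayscale frame, got shape {pixels.shape}"
        )
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    kwargs = {
        "pixel_size_um": meta.get("pixel_size_um", defaults.get("pixel_size_um", PIXEL_SIZE_UM)),
        "filter": meta.get("filter", defaults.get("filter", "BP")),
        "case_id": meta.get("case_id", defaults.get("case_id", "")),
        "image_id": meta.get("image_id", defaults.get("image_id", path.stem)),
        "acquisition": meta.get("acquisition", defaults.get("acquisition", "ex_vivo")),
        "meta": meta.get("meta", {}),
    }
    if pixels.shape != IMAGE_SHAPE:
        if not allow_any_size:
            raise DimensionError(
                f"{path.name}: expected {IMAGE_SHAPE}, got {pixels.shape} "
                "(pass allow_any_size=True to accept)"
            )
        kwargs["meta"]["size_override"] = True
    return FieldImage(pixels=pixels, **kwargs)


def read_ground_truth(path: str | Path) -> GroundTruth | None:
    """Load the ground-truth annotations from a frame's sidecar, if present."""
    sidecar = _sidecar_path(Path(path))
    if not sidecar.exists():
        return None
    meta = json.loads(sidecar.read_text())
    if "ground_truth" not in meta:
        return None
    return GroundTruth.from_dict(meta["ground_truth"])


def read_scene_spec(path: str | Path) -> SceneSpec | None:
    sidecar = _sidecar_path(Path(path))
    if not sidecar.exists():
        return None
    meta = json.loads(sidecar.read_text())
    if "scene_spec" not in meta:
        return None
    return SceneSpec.from_dict(meta["scene_spec"])
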