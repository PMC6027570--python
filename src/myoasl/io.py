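"""Readers and writers for FAIR-ASL series, masks, label maps and results.

One ASL scan is stored as a 14-frame NIfTI-1 volume — base image, noise
image, then six interleaved control/label pairs in acquisition order — with
a JSON sidecar for the scan metadata (heart rate, post-labeling delay in RR
intervals, blood T1, pixel spacing).  Masks and AHA label maps are integer
NIfTI volumes on the same grid with a sidecar carrying the LV center and the
RV insertion angle.  Cohort results travel as a long-format CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ASLSeries",
    "MyocardialMask",
    "N_PAIRS",
    "RESULT_COLUMNS",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "read_results",
    "write_results",
    "load_config",
    "save_config",
]

N_PAIRS = 6
N_FRAMES = 2 + 2 * N_PAIRS  # base, noise, then interleaved control/label

DEFAULT_T1_BLOOD_MS = 1650.0  # longitudinal relaxation of blood at 3T
DEFAULT_N_RR_DELAY = 2  # post-labeling delay in cardiac RR intervals

RESULT_COLUMNS = [
    "subject",
    "slice",
    "segment",
    "region",
    "condition",
    "timepoint",
    "mbf",
    "pn",
    "tsnr",
    "included",
]


@dataclass
class ASLSeries:
    """One slice's FAIR-ASL acquisition.

    Attributes
    ----------
    base_image : ndarray
        Image acquired without a labeling pulse (signal normalization B).
    noise_image : ndarray
        Noise-only image from the same breath-hold.
    pairs : list of (control, label) ndarray tuples
        Exactly six control/label image pairs.
    heart_rate : float
        Beats per minute recorded during the scan; sets the post-labeling
        delay T_D = n_rr_delay * 60000 / heart_rate in ms.
    """

    base_image: np.ndarray
    noise_image: np.ndarray
    pairs: list[tuple[np.ndarray, np.ndarray]]
    heart_rate: float
    n_rr_delay: int = DEFAULT_N_RR_DELAY
    t1_blood: float = DEFAULT_T1_BLOOD_MS
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.base_image = np.asarray(self.base_image, dtype=float)
        self.noise_image = np.asarray(self.noise_image, dtype=float)
        self.pairs = [
            (np.asarray(c, dtype=float), np.asarray(l, dtype=float))
            for c, l in self.pairs
        ]
        if len(self.pairs) != N_PAIRS:
            raise ValueError(f"expected exactly {N_PAIRS} control/label pairs, got {len(self.pairs)}")
        shape = self.base_image.shape
        for img in [self.noise_image] + [im for p in self.pairs for im in p]:
            if img.shape != shape:
                raise ValueError(f"all images must share grid {shape}, got {img.shape}")
        if not self.heart_rate > 0:
            raise ValueError("heart_rate must be positive")
        if not self.t1_blood > 0:
            raise ValueError("t1_blood must be positive")
        if self.n_rr_delay < 1:
            raise ValueError("n_rr_delay must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.base_image.shape

    def control_stack(self) -> np.ndarray:
        return np.stack([c for c, _ in self.pairs])

    def label_stack(self) -> np.ndarray:
        return np.stack([l for _, l in self.pairs])


@dataclass
class MyocardialMask:
    """Boolean LV myocardium mask with LV center and RV insertion reference.

    Angles are degrees counter-clockwise from the +col axis in the displayed
    image; coordinates are 0-based (row, col).
    """

    mask: np.ndarray
    lv_center: tuple[float, float]
    rv_insertion_angle: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("myocardial mask is empty")
        r0, c0 = self.lv_center
        ri, ci = int(round(r0)), int(round(c0))
        if (
            0 <= ri < self.mask.shape[0]
            and 0 <= ci < self.mask.shape[1]
            and self.mask[ri, ci]
        ):
            raise ValueError("lv_center lies inside the mask; expected blood pool outside the myocardium")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _save_nifti(data: np.ndarray, path: Path, pixel_spacing: float, dtype) -> None:
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))


def write_series(series: ASLSeries, path) -> Path:
    """Write an ASLSeries as a 14-frame NIfTI plus JSON sidecar."""
    path = Path(path)
    frames = [series.base_image, series.noise_image]
    for c, l in series.pairs:
        frames.extend([c, l])
    vol = np.stack(frames, axis=-1)  # (rows, cols, 14)
    _save_nifti(vol, path, series.pixel_spacing, np.float64)
    meta = {
        "heart_rate": series.heart_rate,
        "n_rr_delay": series.n_rr_delay,
        "t1_blood": series.t1_blood,
        "pixel_spacing": series.pixel_spacing,
        "frame_layout": "base, noise, C1, L1, ..., C6, L6",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_series(path) -> ASLSeries:
    """Read a series written by :func:`write_series`.

    Missing optional metadata is filled with defaults (``n_rr_delay=2``,
    ``t1_blood=1650`` ms); a missing heart rate is an error since no default
    is physiologically safe.
    """
    path = Path(path)
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if vol.ndim != 3 or vol.shape[-1] != N_FRAMES:
        raise ValueError(
            f"expected a {N_FRAMES}-frame volume (base, noise, then 6 interleaved "
            f"control/label pairs); got shape {vol.shape}"
        )
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "heart_rate" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks heart_rate; no default is safe")
    pairs = [(vol[..., 2 + 2 * i], vol[..., 3 + 2 * i]) for i in range(N_PAIRS)]
    return ASLSeries(
        base_image=vol[..., 0],
        noise_image=vol[..., 1],
        pairs=pairs,
        heart_rate=float(meta["heart_rate"]),
        n_rr_delay=int(meta.get("n_rr_delay", DEFAULT_N_RR_DELAY)),
        t1_blood=float(meta.get("t1_blood", DEFAULT_T1_BLOOD_MS)),
        pixel_spacing=float(meta.get("pixel_spacing", 1.0)),
    )


def write_mask(mask: MyocardialMask, path, pixel_spacing: float = 1.0) -> Path:
    path = Path(path)
    _save_nifti(mask.mask.astype(np.uint8), path, pixel_spacing, np.uint8)
    meta = {
        "lv_center": list(mask.lv_center),
        "rv_insertion_angle": mask.rv_insertion_angle,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_mask(path, series_shape: tuple[int, int] | None = None) -> MyocardialMask:
    path = Path(path)
    data = np.asarray(nib.load(str(path)).dataobj)
    if series_shape is not None and data.shape != tuple(series_shape):
        raise ValueError(f"mask grid {data.shape} does not match series grid {tuple(series_shape)}")
    meta = json.loads(_sidecar_path(path).read_text())
    return MyocardialMask(
        mask=data > 0,
        lv_center=tuple(meta["lv_center"]),
        rv_insertion_angle=float(meta["rv_insertion_angle"]),
    )


def write_labels(labels, path, pixel_spacing: float = 1.0) -> Path:
    """Write a SegmentLabels map as an integer NIfTI plus sidecar."""
    path = Path(path)
    _save_nifti(labels.labels.astype(np.int16), path, pixel_spacing, np.int16)
    meta = {
        "lv_center": list(labels.lv_center),
        "rv_insertion_angle": labels.rv_insertion_angle,
        "segments": {str(k): v for k, v in labels.regions.items()},
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_labels(path, series_shape: tuple[int, int] | None = None):
    from .segmentation import SegmentLabels

    path = Path(path)
    data = np.asarray(nib.load(str(path)).dataobj).astype(int)
    if series_shape is not None and data.shape != tuple(series_shape):
        raise ValueError(f"label grid {data.shape} does not match series grid {tuple(series_shape)}")
    meta = json.loads(_sidecar_path(path).read_text())
    return SegmentLabels(
        labels=data,
        lv_center=tuple(meta.get("lv_center", (0.0, 0.0))),
        rv_insertion_angle=float(meta.get("rv_insertion_angle", 0.0)),
    )


def write_results(cohort_table: pd.DataFrame, path) -> Path:
    """Write the long-format per-segment results table.

    One row per (subject, slice, segment, condition, timepoint); excluded
    segments retain their values with ``included=False`` — exclusion is a
    flag, never a deletion.
    """
    path = Path(path)
    missing = [c for c in RESULT_COLUMNS if c not in cohort_table.columns]
    if missing:
        raise ValueError(f"results table lacks columns {missing}")
    cohort_table.to_csv(path, index=False, columns=RESULT_COLUMNS)
    return path


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["included"] = df["included"].astype(bool)
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return path
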