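"""Domain types and case-bundle I/O.

A *case* holds everything known about one subject: the co-aligned MR
volumes and derived parametric maps, the tumor volume of interest (VOI),
the plane of interest (POI) matching the primary histologic section, a
categorical histologic viability map, the control points relating the two
coordinate frames, and the pathologist-style necrosis percentage.

Volumes are stored as NIfTI (via :mod:`nibabel`); control points as CSV;
the manifest and scalar metadata as YAML.  All lattices are 0-based with
``physical = origin + index * spacing`` and planes are coronal by
convention (slices are indexed along the last axis).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Viability labels
# ---------------------------------------------------------------------------

NON_TUMOR = 0
VIABLE = 1
NECROTIC = 2

LABEL_NAMES = {NON_TUMOR: "non_tumor", VIABLE: "viable", NECROTIC: "necrotic"}

# Image-type abbreviations, in canonical order. The first three are the
# conventional sequences; the rest are derived parametric maps.
PC = "PC"
T1 = "T1"
STIR = "STIR"
ADC = "ADC"
DCE_SUB_0 = "DCE-sub-0"
DCE_SUB_1 = "DCE-sub-1"
DCE_SUB_2 = "DCE-sub-2"
DCE_SLOPE = "DCE-slope"
DCE_AUC = "DCE-AUC"
DCE_KTRANS = "DCE-Ktrans"
DCE_VE = "DCE-ve"

IMAGE_TYPES = (
    PC, T1, STIR, ADC,
    DCE_SUB_0, DCE_SUB_1, DCE_SUB_2,
    DCE_SLOPE, DCE_AUC, DCE_KTRANS, DCE_VE,
)

CONV_TYPES = (PC, T1, STIR)
DW_TYPES = (ADC,)
DCE_S_TYPES = (DCE_SUB_0, DCE_SUB_1, DCE_SUB_2)
DCE_Q_TYPES = (DCE_SLOPE, DCE_AUC, DCE_KTRANS, DCE_VE)


class CaseLoadError(RuntimeError):
    """A required file of a case bundle is missing or unreadable."""


class AlignmentError(RuntimeError):
    """Two grids that must share a lattice do not."""


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

@dataclass
class ImageGrid:
    """A real scalar field on a 2-D or 3-D integer lattice.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny)`` or ``(nx, ny, nz)``.
    spacing
        Physical size of one lattice step per axis, in mm.  All > 0.
    origin
        Physical coordinate of lattice index ``(0, 0[, 0])``, in mm.
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise ValueError("ImageGrid must be 2-D or 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)[: self.values.ndim]
        self.origin = tuple(float(o) for o in self.origin)[: self.values.ndim]
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self):
        return self.values.shape

    def validate_finite(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in image grid")
        return self

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        return ImageGrid(values, self.spacing, self.origin)


@dataclass
class MaskGrid:
    """Binary field on the same lattice as a companion image.

    ``role`` is ``"VOI"`` for the 3-D tumor volume or ``"AOI"`` for the
    2-D tumor cross section on the plane of interest.
    """

    values: np.ndarray
    role: str = "VOI"
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)[: self.values.ndim]
        self.origin = tuple(float(o) for o in self.origin)[: self.values.ndim]

    @property
    def shape(self):
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class ViabilityMap:
    """Categorical field with labels {non_tumor, viable, necrotic}.

    Typically lives on a finer lattice than the MR images (histology
    resolution); ``non_tumor`` includes void / tissue-loss areas.
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0)
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int16)
        bad = set(np.unique(self.values)) - set(LABEL_NAMES)
        if bad:
            raise ValueError(f"unknown viability labels: {sorted(bad)}")
        self.spacing = tuple(float(s) for s in self.spacing)[: self.values.ndim]
        self.origin = tuple(float(o) for o in self.origin)[: self.values.ndim]

    @property
    def shape(self):
        return self.values.shape

    def necrosis_percent(self) -> float:
        """Percent necrosis among tumor (necrotic + viable) pixels."""
        nec = int((self.values == NECROTIC).sum())
        via = int((self.values == VIABLE).sum())
        if nec + via == 0:
            raise ValueError("map contains no tumor pixels")
        return 100.0 * nec / (nec + via)


@dataclass
class AcquisitionParams:
    """DCE acquisition record for the spoiled-gradient-echo signal model.

    ``relaxivity`` is stored as printed in the protocol (0.0039 in
    L mol^-1 s^-1); ``relaxivity_interpretation`` selects how it is turned
    into an effective per-mM relaxivity, because the printed figure is
    dimensionally inconsistent with typical Gd-DOTA values (~3.9
    L mmol^-1 s^-1): ``"per_mmol"`` (default) reads it as 3.9 L/mmol/s,
    ``"as_printed"`` reads it literally.
    """

    tr: float = 5.07e-3            # s
    flip_angle: float = 15.0       # degrees
    relaxivity: float = 0.0039
    relaxivity_interpretation: str = "per_mmol"
    t1_blood: float = 1.6          # s
    t1_tissue: float = 1.1         # s

    @property
    def r1_per_mm(self) -> float:
        """Effective relaxivity in s^-1 per mM of contrast agent."""
        if self.relaxivity_interpretation == "per_mmol":
            return self.relaxivity * 1000.0
        if self.relaxivity_interpretation == "as_printed":
            return self.relaxivity / 1000.0
        raise ValueError(
            f"unknown relaxivity interpretation "
            f"{self.relaxivity_interpretation!r}"
        )


@dataclass
class DCESeries:
    """An ordered dynamic contrast-enhanced series.

    The first frame is pre-contrast; ``timestamps`` are seconds from that
    frame and strictly increasing; ``sampling_interval`` is the nominal
    frame spacing T.
    """

    frames: list            # list[ImageGrid]
    timestamps: np.ndarray  # s
    sampling_interval: float = 19.5
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if len(self.frames) != len(self.timestamps):
            raise ValueError("frames and timestamps must align")
        if len(self.timestamps) and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """Stack frames along a new leading time axis."""
        return np.stack([f.values for f in self.frames], axis=0)


@dataclass
class SubsetSpec:
    """A named combination of MR image types entering the fusion."""

    name: str
    members: tuple

    def __post_init__(self):
        self.members = tuple(self.members)
        unknown = set(self.members) - set(IMAGE_TYPES)
        if unknown:
            raise ValueError(f"unknown image types {sorted(unknown)}")

    @property
    def s(self) -> int:
        return len(self.members)


#: The eight MRI subsets whose fusion weights are optimized.
SUBSETS = {
    "CONV": SubsetSpec("CONV", CONV_TYPES),
    "DW": SubsetSpec("DW", DW_TYPES),
    "DCE-q": SubsetSpec("DCE-q", DCE_Q_TYPES),
    "DW+DCE-q": SubsetSpec("DW+DCE-q", DW_TYPES + DCE_Q_TYPES),
    "CONV+DW": SubsetSpec("CONV+DW", CONV_TYPES + DW_TYPES),
    "CONV+DCE-q": SubsetSpec("CONV+DCE-q", CONV_TYPES + DCE_Q_TYPES),
    "CONV+DW+DCE-q": SubsetSpec(
        "CONV+DW+DCE-q", CONV_TYPES + DW_TYPES + DCE_Q_TYPES),
    "CONV+DW+DCE-q+DCE-s": SubsetSpec(
        "CONV+DW+DCE-q+DCE-s",
        CONV_TYPES + DW_TYPES + DCE_Q_TYPES + DCE_S_TYPES),
}


@dataclass
class MRICase:
    """All co-aligned data for one subject."""

    case_id: str
    images: dict = field(default_factory=dict)   # image type -> ImageGrid
    dwi: list = field(default_factory=list)      # [(b_value, ImageGrid)]
    dce: Optional[DCESeries] = None
    voi: Optional[MaskGrid] = None
    poi_index: int = 0
    histology: Optional[ViabilityMap] = None
    control_points: Optional[pd.DataFrame] = None  # x_hist,y_hist,x_mr,y_mr
    n_hist: Optional[float] = None               # percent necrosis [0, 100]
    artery_mask: Optional[MaskGrid] = None

    def aoi(self) -> MaskGrid:
        """Tumor cross section of the VOI along the plane of interest."""
        if self.voi is None:
            raise ValueError("case has no VOI")
        plane = self.voi.values[:, :, self.poi_index]
        return MaskGrid(plane, role="AOI", spacing=self.voi.spacing[:2],
                        origin=self.voi.origin[:2])

    def poi_image(self, image_type: str) -> ImageGrid:
        """2-D slice of an image volume on the plane of interest."""
        grid = self.images[image_type]
        return ImageGrid(grid.values[:, :, self.poi_index],
                         grid.spacing[:2], grid.origin[:2])

    def validate(self) -> "MRICase":
        if self.voi is not None:
            for name, grid in self.images.items():
                if grid.shape != self.voi.shape:
                    raise AlignmentError(
                        f"image {name!r} lattice {grid.shape} does not match "
                        f"VOI lattice {self.voi.shape}")
        for name, grid in self.images.items():
            try:
                grid.validate_finite()
            except ValueError as exc:
                raise CaseLoadError(f"image {name!r}: {exc}") from exc
        return self


# ---------------------------------------------------------------------------
# NIfTI helpers
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing):
        aff[i, i] = s
    for i, o in enumerate(origin):
        aff[i, 3] = o
    return aff


def write_nifti(path: str, values: np.ndarray, spacing, origin,
                dtype=None) -> None:
    data = np.asarray(values)
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, _affine(spacing, origin))
    nib.save(img, path)


def read_nifti(path: str):
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    aff = img.affine
    ndim = data.ndim if data.ndim <= 3 else 3
    spacing = tuple(float(aff[i, i]) for i in range(ndim))
    origin = tuple(float(aff[i, 3]) for i in range(ndim))
    return data, spacing, origin


def write_viability_map(vmap: ViabilityMap, path: str) -> None:
    """Write a categorical viability map (labels kept exactly)."""
    if vmap.values.size == 0:
        raise ValueError("refusing to write an empty viability map")
    write_nifti(path, vmap.values, vmap.spacing, vmap.origin, dtype=np.int16)


def read_viability_map(path: str) -> ViabilityMap:
    data, spacing, origin = read_nifti(path)
    return ViabilityMap(np.asarray(data, dtype=np.int16), spacing, origin)


# ---------------------------------------------------------------------------
# Case bundles: one directory per case with a YAML manifest
# ---------------------------------------------------------------------------

def save_case(case: MRICase, directory: str) -> None:
    """Write a case as a loadable bundle (NIfTI + CSV + YAML manifest)."""
    os.makedirs(directory, exist_ok=True)
    manifest = {"case_id": case.case_id, "poi_index": int(case.poi_index),
                "images": {}, "dwi": [], "n_hist": case.n_hist}
    for name, grid in case.images.items():
        fname = f"{name}.nii.gz"
        write_nifti(os.path.join(directory, fname), grid.values,
                    grid.spacing, grid.origin)
        manifest["images"][name] = fname
    for b, grid in case.dwi:
        fname = f"dwi_b{int(b)}.nii.gz"
        write_nifti(os.path.join(directory, fname), grid.values,
                    grid.spacing, grid.origin)
        manifest["dwi"].append({"b": float(b), "file": fname})
    if case.voi is not None:
        write_nifti(os.path.join(directory, "voi.nii.gz"),
                    case.voi.values.astype(np.int16), case.voi.spacing,
                    case.voi.origin)
        manifest["voi"] = "voi.nii.gz"
    if case.artery_mask is not None:
        write_nifti(os.path.join(directory, "artery.nii.gz"),
                    case.artery_mask.values.astype(np.int16),
                    case.artery_mask.spacing, case.artery_mask.origin)
        manifest["artery"] = "artery.nii.gz"
    if case.histology is not None:
        write_viability_map(case.histology,
                            os.path.join(directory, "histology.nii.gz"))
        manifest["histology"] = "histology.nii.gz"
    if case.control_points is not None:
        case.control_points.to_csv(
            os.path.join(directory, "control_points.csv"), index=False)
        manifest["control_points"] = "control_points.csv"
    if case.dce is not None:
        arr = np.moveaxis(case.dce.as_array(), 0, -1)  # x,y,z,t
        f0 = case.dce.frames[0]
        write_nifti(os.path.join(directory, "dce.nii.gz"), arr,
                    f0.spacing, f0.origin)
        manifest["dce"] = {
            "file": "dce.nii.gz",
            "timestamps": [float(t) for t in case.dce.timestamps],
            "sampling_interval": float(case.dce.sampling_interval),
            "acquisition": dataclasses.asdict(case.dce.acquisition),
        }
    with open(os.path.join(directory, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_case(directory: str) -> MRICase:
    """Load a case bundle written by :func:`save_case`.

    Missing optional modalities (DCE, histology, control points) are
    recorded as absent; a missing file named by the manifest raises
    :class:`CaseLoadError` naming the image type, and a lattice mismatch
    raises :class:`AlignmentError`.
    """
    man_path = os.path.join(directory, "manifest.yaml")
    if not os.path.exists(man_path):
        raise CaseLoadError(f"no manifest.yaml in {directory}")
    with open(man_path) as fh:
        manifest = yaml.safe_load(fh)

    def _load(fname, what):
        path = os.path.join(directory, fname)
        if not os.path.exists(path):
            raise CaseLoadError(f"missing file for {what!r}: {fname}")
        return read_nifti(path)

    case = MRICase(case_id=str(manifest["case_id"]),
                   poi_index=int(manifest.get("poi_index", 0)),
                   n_hist=manifest.get("n_hist"))
    for name, fname in (manifest.get("images") or {}).items():
        data, spacing, origin = _load(fname, name)
        case.images[name] = ImageGrid(data, spacing, origin)
    for entry in manifest.get("dwi") or []:
        data, spacing, origin = _load(entry["file"], f"DWI b={entry['b']}")
        case.dwi.append((float(entry["b"]), ImageGrid(data, spacing, origin)))
    if "voi" in manifest:
        data, spacing, origin = _load(manifest["voi"], "VOI")
        case.voi = MaskGrid(data, role="VOI", spacing=spacing, origin=origin)
    if "artery" in manifest:
        data, spacing, origin = _load(manifest["artery"], "artery")
        case.artery_mask = MaskGrid(data, role="artery", spacing=spacing,
                                    origin=origin)
    if "histology" in manifest:
        path = os.path.join(directory, manifest["histology"])
        if not os.path.exists(path):
            raise CaseLoadError("missing file for 'histology'")
        case.histology = read_viability_map(path)
    if "control_points" in manifest:
        case.control_points = pd.read_csv(
            os.path.join(directory, manifest["control_points"]))
    if "dce" in manifest:
        meta = manifest["dce"]
        data, spacing, origin = _load(meta["file"], "DCE")
        frames = [ImageGrid(data[..., k], spacing[:3], origin[:3])
                  for k in range(data.shape[-1])]
        case.dce = DCESeries(
            frames, np.asarray(meta["timestamps"], dtype=float),
            sampling_interval=float(meta["sampling_interval"]),
            acquisition=AcquisitionParams(**meta["acquisition"]))
    return case.validate()
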