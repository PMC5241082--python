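"""Readers, writers and run configuration.

File formats:

* DWI: NIfTI volume (4D) + tab-separated gradient table with columns
  ``b_s_mm2, u_AP, u_RL, u_SI`` (one row per acquisition) + optional JSON
  metadata sidecar.  All NIfTI affines written by this package map voxel
  indices directly to magnet (AP, RL, SI) millimeters — NOT to RAS — and
  the convention is recorded in the sidecar.
* "DICOM-like" bundles: a JSON sidecar of standard-tag values
  (ImagePositionPatient / ImageOrientationPatient / PixelSpacing /
  SpacingBetweenSlices in the LPS patient frame, plus per-acquisition
  b-values and directions) next to the voxel data; the LPS -> (AP, RL, SI)
  conversion is a pure axis permutation (AP = +P, RL = +L, SI = +S).
* Tensor fields: 4D NIfTI with 9 components (row-major L_ij) on the last
  axis; correctors: scalar NIfTI; profiles/coefficients/summaries: TSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .adc import ADC_CLIP_RANGE, ADCMap, DWISeries
from .corrector import CorrectorMap, DirectionSchema
from .grids import GridSpec, ImageGeometry
from .roi import HIST_RANGE, HIST_STEP
from .tensor import NonlinearityTensorField

_FRAME_NOTE = "voxel->mm affine is in magnet (AP,RL,SI) frame, not RAS"


def _geometry_affine(geometry: ImageGeometry) -> np.ndarray:
    return geometry.affine


def write_dwi(series: DWISeries, prefix: str | Path) -> dict[str, Path]:
    """Write NIfTI + gradient table + JSON sidecar; returns written paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nii = prefix.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(series.data, _geometry_affine(series.geometry)), nii)
    btab = prefix.with_suffix(".btab")
    lines = ["b_s_mm2\tu_AP\tu_RL\tu_SI"]
    for b, u in zip(series.bvals, series.bvecs):
        lines.append(f"{b:g}\t{u[0]:.10g}\t{u[1]:.10g}\t{u[2]:.10g}")
    btab.write_text("\n".join(lines) + "\n")
    meta = dict(series.meta)
    meta["coordinate_frame"] = _FRAME_NOTE
    if series.schema is not None:
        meta["schema"] = {"name": series.schema.name, "U": series.schema.U.tolist()}
    sidecar = prefix.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1, default=float))
    return {"nifti": nii, "btab": btab, "sidecar": sidecar}


def _read_btab(path: Path) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("b_s_mm2", "#")):
            continue
        rows.append([float(v) for v in line.split("\t")])
    arr = np.asarray(rows, float)
    return arr[:, 0], arr[:, 1:4]


def read_dwi(prefix: str | Path) -> DWISeries:
    """Read a DWI bundle written by :func:`write_dwi` (or compatible)."""
    prefix = Path(prefix)
    if prefix.is_dir():
        return read_dwi_dicomlike(prefix)
    nii = nib.load(prefix.with_suffix(".nii.gz"))
    data = np.asarray(nii.dataobj, float)
    bvals, bvecs = _read_btab(prefix.with_suffix(".btab"))
    geometry = ImageGeometry(np.asarray(nii.affine), data.shape[:3])
    schema = None
    meta = {}
    sidecar = prefix.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sch = meta.pop("schema", None)
        if sch is not None:
            schema = DirectionSchema(sch["name"], np.asarray(sch["U"]))
    return DWISeries(data, bvals, bvecs, geometry, schema=schema, meta=meta)


_LPS_TO_APRLSI = np.array(
    [[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]
)  # (AP, RL, SI) = (P, L, S)


def read_dwi_dicomlike(directory: str | Path) -> DWISeries:
    """Read a synthetic DICOM-like bundle: JSON header sidecar + NIfTI data.

    The sidecar (``dicom.json``) mimics the standard DICOM geometry and
    diffusion tags in the LPS patient frame; geometry is rebuilt from
    ImagePositionPatient / ImageOrientationPatient / PixelSpacing /
    SpacingBetweenSlices and converted to the magnet (AP, RL, SI) frame.
    """
    directory = Path(directory)
    hdr = json.loads((directory / "dicom.json").read_text())
    data = np.asarray(nib.load(directory / "data.nii.gz").dataobj, float)
    iop = np.asarray(hdr["ImageOrientationPatient"], float)  # row & col cosines
    row, col = iop[:3], iop[3:]
    normal = np.cross(row, col)
    dr, dc = hdr["PixelSpacing"]
    ds = hdr["SpacingBetweenSlices"]
    ipp = np.asarray(hdr["ImagePositionPatient"], float)
    aff_lps = np.eye(4)
    aff_lps[:3, 0] = row * dr
    aff_lps[:3, 1] = col * dc
    aff_lps[:3, 2] = normal * ds
    aff_lps[:3, 3] = ipp
    aff = np.eye(4)
    aff[:3, :] = _LPS_TO_APRLSI @ aff_lps[:3, :]
    geometry = ImageGeometry(aff, data.shape[:3])
    bvals = np.asarray(hdr["DiffusionBValues"], float)
    bvecs_lps = np.asarray(hdr["DiffusionGradientOrientations"], float)
    bvecs = bvecs_lps @ _LPS_TO_APRLSI.T
    schema = None
    if "SchemaName" in hdr:
        U = np.stack(
            [bvecs[i] for i in range(len(bvals)) if bvals[i] > 0][:3], axis=1
        )
        schema = DirectionSchema(hdr["SchemaName"], U)
    return DWISeries(data, bvals, bvecs, geometry, schema=schema, meta={"source": "dicom-like"})


def write_dicomlike(series: DWISeries, directory: str | Path) -> Path:
    """Write the synthetic DICOM-like bundle (test/round-trip companion)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = series.geometry.affine
    aff_lps = np.eye(4)
    aff_lps[:3, :] = _LPS_TO_APRLSI.T @ aff[:3, :]  # permutation is its own inverse pair
    dr = float(np.linalg.norm(aff_lps[:3, 0]))
    dc = float(np.linalg.norm(aff_lps[:3, 1]))
    normal = np.cross(aff_lps[:3, 0] / dr, aff_lps[:3, 1] / dc)
    # signed spacing: negative when the stack runs against the slice normal
    ds = float(normal @ aff_lps[:3, 2])
    hdr = {
        "ImagePositionPatient": aff_lps[:3, 3].tolist(),
        "ImageOrientationPatient": (aff_lps[:3, 0] / dr).tolist()
        + (aff_lps[:3, 1] / dc).tolist(),
        "PixelSpacing": [dr, dc],
        "SpacingBetweenSlices": ds,
        "DiffusionBValues": series.bvals.tolist(),
        "DiffusionGradientOrientations": (series.bvecs @ _LPS_TO_APRLSI).tolist(),
    }
    if series.schema is not None:
        hdr["SchemaName"] = series.schema.name
    (directory / "dicom.json").write_text(json.dumps(hdr, indent=1))
    nib.save(nib.Nifti1Image(series.data, aff), directory / "data.nii.gz")
    return directory


def write_tensor_field(field: NonlinearityTensorField, path: str | Path) -> Path:
    path = Path(path)
    data = field.tensor.reshape(field.grid.shape + (9,))
    aff = np.eye(4)
    aff[:3, :3] = np.diag(field.grid.spacing)
    aff[:3, 3] = field.grid.origin
    nib.save(nib.Nifti1Image(data, aff), path)
    return path


def read_tensor_field(path: str | Path) -> NonlinearityTensorField:
    nii = nib.load(path)
    data = np.asarray(nii.dataobj, float)
    aff = np.asarray(nii.affine)
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("tensor-field NIfTI must be axis-aligned")
    grid = GridSpec(
        tuple(aff[:3, 3]), tuple(np.diag(aff[:3, :3])), data.shape[:3]
    )
    return NonlinearityTensorField(grid, data.reshape(grid.shape + (3, 3)))


def write_corrector(c: CorrectorMap, path: str | Path) -> Path:
    path = Path(path)
    if c.grid is not None:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(c.grid.spacing)
        aff[:3, 3] = c.grid.origin
    else:
        aff = c.geometry.affine
    nib.save(nib.Nifti1Image(c.values, aff), path)
    return path


def read_corrector(path: str | Path, kind: str = "average") -> CorrectorMap:
    nii = nib.load(path)
    data = np.asarray(nii.dataobj, float)
    aff = np.asarray(nii.affine)
    diag = np.diag(aff[:3, :3])
    if np.allclose(aff[:3, :3], np.diag(diag)):
        grid = GridSpec(tuple(aff[:3, 3]), tuple(diag), data.shape)
        return CorrectorMap(data, kind, grid=grid)
    return CorrectorMap(data, kind, geometry=ImageGeometry(aff, data.shape))


def write_adc(adc: ADCMap, path: str | Path, provenance: dict | None = None) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(adc.values, adc.geometry.affine), path)
    side = dict(provenance or {})
    side["coordinate_frame"] = _FRAME_NOTE
    side["clip_range"] = list(ADC_CLIP_RANGE)
    Path(str(path) + ".json").write_text(json.dumps(side, indent=1, default=float))
    return path


def read_adc(path: str | Path) -> ADCMap:
    nii = nib.load(path)
    data = np.asarray(nii.dataobj, float)
    geometry = ImageGeometry(np.asarray(nii.affine), data.shape)
    lo, hi = ADC_CLIP_RANGE
    mask = (data >= lo) & (data <= hi)
    return ADCMap(np.where(mask, data, 0.0), mask, geometry)


def file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclasses.dataclass
class RunConfig:
    """Serializable run configuration with protocol defaults.

    Numeric defaults mirror the shared analysis protocol: 0.02-wide
    histogram bins on 1-2.5, the 0.5-3.3 plausibility window, and the
    largest acquired b-value as the high shell.
    """

    schema: str = "LAB"
    bin_step: float = HIST_STEP
    hist_range: tuple[float, float] = HIST_RANGE
    clip_range: tuple[float, float] = ADC_CLIP_RANGE
    b_high: float | None = None  # None -> max acquired b
    grid_fov_mm: float = 600.0
    grid_spacing_mm: float = 5.0
    seed: int = 0
    version: int = 1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["hist_range"] = tuple(d["hist_range"])
        d["clip_range"] = tuple(d["clip_range"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
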