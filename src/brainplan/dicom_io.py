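"""DICOM and internal-format I/O for CT series, structure sets and RT plans.

All readers deliver data in the package-wide convention: axis-aligned grids
indexed (x, y, z) in patient LPS millimetres.  Non-axis-aligned CT series are
resampled to axis-aligned at read time (linear for HU); the downstream
similarity score needs well-defined anterior-posterior and superior-inferior
axes.

RT plans are handled conservatively: :class:`PlanTemplate` wraps the full
pydicom dataset and exposes only the fields the pipeline edits (patient
identity, identifiers, isocenter).  Everything else — beams, MLC sequences,
monitor units — passes through untouched, which is the point of reusing a
validated template plan.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .core import BinaryMask, CTVolume, ImageGeometry

__all__ = [
    "StructureSet",
    "PlanTemplate",
    "read_ct_series",
    "write_ct_series",
    "read_structure_set",
    "write_structure_set",
    "read_plan",
    "write_plan",
    "make_template_plan",
    "save_volume",
    "load_volume",
    "save_structure_set_npz",
    "load_structure_set_npz",
]

CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"
RTPLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.5"

STANDARD_STRUCTURES = ("brain", "eye_L", "eye_R", "lens_L", "lens_R", "external")


@dataclass
class StructureSet:
    """Named binary masks sharing one grid geometry."""

    masks: dict[str, BinaryMask]

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("structure set is empty")
        geoms = {m.geometry for m in self.masks.values()}
        shapes = {m.shape for m in self.masks.values()}
        if len(geoms) > 1 or len(shapes) > 1:
            raise ValueError("all masks in a structure set must share one geometry")

    @property
    def geometry(self) -> ImageGeometry:
        return next(iter(self.masks.values())).geometry

    def __getitem__(self, name: str) -> BinaryMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)


class PlanTemplate:
    """An RT plan: beam/MLC settings kept opaque, identity fields editable."""

    def __init__(self, dataset: Dataset):
        if getattr(dataset, "Modality", None) != "RTPLAN" and \
                getattr(dataset, "SOPClassUID", None) != RTPLAN_STORAGE:
            raise ValueError("dataset is not an RT plan")
        beams = getattr(dataset, "BeamSequence", None)
        if not beams:
            raise ValueError("RT plan has no beams")
        self.dataset = dataset

    # -- read-only views -------------------------------------------------
    @property
    def patient_name(self) -> str:
        return str(self.dataset.PatientName)

    @property
    def patient_id(self) -> str:
        return str(self.dataset.PatientID)

    @property
    def beams(self) -> list[Dataset]:
        return list(self.dataset.BeamSequence)

    @property
    def isocenter_mm(self) -> np.ndarray:
        iso = self._find_isocenter()
        if iso is None:
            raise ValueError("plan has no isocenter")
        return iso

    def _find_isocenter(self) -> np.ndarray | None:
        for beam in self.dataset.BeamSequence:
            for cp in getattr(beam, "ControlPointSequence", []):
                if hasattr(cp, "IsocenterPosition"):
                    return np.asarray([float(v) for v in cp.IsocenterPosition])
        return None

    # -- editing (used by plan retargeting only) -------------------------
    def copy(self) -> "PlanTemplate":
        return PlanTemplate(copy.deepcopy(self.dataset))

    def set_patient(self, name: str, patient_id: str) -> None:
        self.dataset.PatientName = name
        self.dataset.PatientID = patient_id

    def set_isocenter(self, iso_mm) -> None:
        iso = [float(v) for v in iso_mm]
        if len(iso) != 3 or not np.all(np.isfinite(iso)):
            raise ValueError("isocenter must be 3 finite coordinates")
        for beam in self.dataset.BeamSequence:
            for cp in getattr(beam, "ControlPointSequence", []):
                if hasattr(cp, "IsocenterPosition"):
                    cp.IsocenterPosition = iso

    def refresh_identifiers(self) -> None:
        ds = self.dataset
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = generate_uid()
        ds.StudyInstanceUID = generate_uid()
        if hasattr(ds, "file_meta"):
            ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID


# ---------------------------------------------------------------------------
# CT series
# ---------------------------------------------------------------------------

def _base_file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_ct_series(ct: CTVolume, directory: str | Path,
                    patient_name: str = "Phantom^Head",
                    patient_id: str = "PH0000") -> list[Path]:
    """Write one DICOM file per axial slice (int16 HU, explicit VR LE)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = ct.shape
    sx, sy, sz = ct.geometry.spacing
    ox, oy, oz = ct.geometry.origin
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    paths = []
    for k in range(nz):
        sop_uid = generate_uid()
        ds = FileDataset(None, {}, file_meta=_base_file_meta(CT_STORAGE, sop_uid),
                         preamble=b"\0" * 128)
        ds.SOPClassUID = CT_STORAGE
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.PatientName = patient_name
        ds.PatientID = patient_id
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [float(ox), float(oy), float(oz + k * sz)]
        ds.PixelSpacing = [float(sy), float(sx)]  # row spacing, column spacing
        ds.SliceThickness = float(sz)
        ds.Rows, ds.Columns = ny, nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed, HU stored directly
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        sl = np.round(ct.voxels[:, :, k].T).astype("<i2")
        ds.PixelData = sl.tobytes()
        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_ct_series(directory: str | Path, spacing_tol: float = 1e-3) -> CTVolume:
    """Read a single coherent CT series from a directory of DICOM files."""
    directory = Path(directory)
    slices = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue
        if getattr(ds, "Modality", None) == "CT":
            slices.append(ds)
    if not slices:
        raise ValueError(f"no CT slices found in {directory}")
    series = {s.SeriesInstanceUID for s in slices}
    if len(series) > 1:
        raise ValueError(f"directory mixes {len(series)} CT series")

    iop = np.asarray([float(v) for v in slices[0].ImageOrientationPatient])
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-4):
        return _read_ct_series_oblique(directory)

    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.asarray([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.ptp(dz) > spacing_tol:
            raise ValueError("non-uniform slice spacing")
        sz = float(dz.mean())
    else:
        sz = float(getattr(slices[0], "SliceThickness", 1.0))
    first = slices[0]
    sy, sx = (float(v) for v in first.PixelSpacing)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    ny, nx = int(first.Rows), int(first.Columns)
    vol = np.empty((nx, ny, len(slices)), dtype=np.float32)
    for k, s in enumerate(slices):
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        vol[:, :, k] = (s.pixel_array.astype(np.float32) * slope + inter).T
    geom = ImageGeometry(spacing_mm=(sx, sy, sz), origin_mm=origin)
    return CTVolume(vol, geom)


def _read_ct_series_oblique(directory: Path) -> CTVolume:
    """Fallback for non-axis-aligned series: resample to axis-aligned (linear)."""
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no readable CT series in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    img = sitk.Resample(
        img, img.GetSize(), sitk.Transform(), sitk.sitkLinear, img.GetOrigin(),
        img.GetSpacing(), (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0), -1000.0,
        sitk.sitkFloat32,
    )
    vol = sitk.GetArrayFromImage(img).astype(np.float32).transpose(2, 1, 0)
    geom = ImageGeometry(spacing_mm=tuple(img.GetSpacing()),
                         origin_mm=tuple(img.GetOrigin()))
    return CTVolume(vol, geom)


# ---------------------------------------------------------------------------
# Structure sets
# ---------------------------------------------------------------------------

def _mask_slice_contours(mask2d: np.ndarray) -> list[np.ndarray]:
    """Closed 0.5-level contours of one axial slice, in (x_index, y_index)."""
    if not mask2d.any():
        return []
    padded = np.pad(mask2d.astype(float), 1)
    out = []
    for c in measure.find_contours(padded, 0.5):
        out.append(c - 1.0)  # undo padding offset
    return out


def write_structure_set(ss: StructureSet, path: str | Path,
                        patient_name: str = "Phantom^Head",
                        patient_id: str = "PH0000") -> Path:
    """Contour masks slice by slice and save as DICOM RTSTRUCT."""
    path = Path(path)
    geom = ss.geometry
    sx, sy, sz = geom.spacing
    ox, oy, oz = geom.origin

    sop_uid = generate_uid()
    ds = FileDataset(None, {}, file_meta=_base_file_meta(RTSTRUCT_STORAGE, sop_uid),
                     preamble=b"\0" * 128)
    ds.SOPClassUID = RTSTRUCT_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.PatientName = patient_name
    ds.PatientID = patient_id
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.StructureSetLabel = "brainplan"

    roi_seq, contour_seq, obs_seq = [], [], []
    for number, (name, mask) in enumerate(ss.masks.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        contours = []
        nz = mask.shape[2]
        for k in range(nz):
            for poly in _mask_slice_contours(mask.voxels[:, :, k]):
                pts = np.empty((len(poly), 3))
                pts[:, 0] = ox + poly[:, 0] * sx
                pts[:, 1] = oy + poly[:, 1] * sy
                pts[:, 2] = oz + k * sz
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(poly)
                c.ContourData = [f"{v:.5f}" for v in pts.ravel()]
                contours.append(c)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = contours
        contour_seq.append(rc)

        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.RTROIInterpretedType = "ORGAN"
        obs_seq.append(obs)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    ds.save_as(path, enforce_file_format=True)
    return path


def _rasterize_polygon(poly_xy_idx: np.ndarray, shape_xy: tuple[int, int]) -> np.ndarray:
    """Voxel-center-inside rasterization of one polygon given in index coords."""
    out = np.zeros(shape_xy, dtype=bool)
    i0 = max(int(np.floor(poly_xy_idx[:, 0].min())), 0)
    i1 = min(int(np.ceil(poly_xy_idx[:, 0].max())) + 1, shape_xy[0])
    j0 = max(int(np.floor(poly_xy_idx[:, 1].min())), 0)
    j1 = min(int(np.ceil(poly_xy_idx[:, 1].max())) + 1, shape_xy[1])
    if i0 >= i1 or j0 >= j1:
        return out
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    centers = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    inside = MplPath(poly_xy_idx).contains_points(centers)
    out[i0:i1, j0:j1] = inside.reshape(ii.shape)
    return out


def read_structure_set(path: str | Path, reference: CTVolume) -> StructureSet:
    """Read an RTSTRUCT and rasterize its contours onto the reference grid."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise ValueError(f"{path} is not an RT structure set")
    geom = reference.geometry
    sx, sy, sz = geom.spacing
    ox, oy, oz = geom.origin
    nx, ny, nz = reference.shape

    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    masks: dict[str, BinaryMask] = {}
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        grid = np.zeros((nx, ny, nz), dtype=bool)
        contours = getattr(rc, "ContourSequence", [])
        if not contours:
            raise ValueError(f"structure {name!r} has no contours")
        for c in contours:
            pts = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            k = int(round((pts[0, 2] - oz) / sz))
            if not 0 <= k < nz:
                raise ValueError(f"contour of {name!r} lies outside the reference grid")
            poly = np.column_stack([(pts[:, 0] - ox) / sx, (pts[:, 1] - oy) / sy])
            grid[:, :, k] |= _rasterize_polygon(poly, (nx, ny))
        masks[name] = BinaryMask(grid, geom)
    if not masks:
        raise ValueError("structure set contains no structures")
    return StructureSet(masks)


# ---------------------------------------------------------------------------
# RT plans
# ---------------------------------------------------------------------------

def read_plan(path: str | Path) -> PlanTemplate:
    ds = pydicom.dcmread(path)
    return PlanTemplate(ds)


def write_plan(plan: PlanTemplate, path: str | Path) -> Path:
    path = Path(path)
    ds = plan.dataset
    if not hasattr(ds, "file_meta") or ds.file_meta is None:
        ds.file_meta = _base_file_meta(RTPLAN_STORAGE, ds.SOPInstanceUID)
    ds.save_as(path, enforce_file_format=True)
    return path


def _mlc_boundaries(n_pairs: int = 10, width_mm: float = 10.0) -> list[float]:
    half = n_pairs * width_mm / 2.0
    return [float(-half + i * width_mm) for i in range(n_pairs + 1)]


def make_template_plan(patient_name: str, patient_id: str,
                       isocenter_mm: tuple[float, float, float],
                       n_leaf_pairs: int = 10) -> PlanTemplate:
    """Two lateral opposed 6 MV beams (gantry 90/270) with rectangular
    placeholder MLC apertures — the template geometry of whole-brain plans."""
    sop_uid = generate_uid()
    ds = FileDataset(None, {}, file_meta=_base_file_meta(RTPLAN_STORAGE, sop_uid),
                     preamble=b"\0" * 128)
    ds.SOPClassUID = RTPLAN_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTPLAN"
    ds.PatientName = patient_name
    ds.PatientID = patient_id
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.RTPlanLabel = "WBRT-template"
    ds.RTPlanGeometry = "PATIENT"

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 10
    fg.NumberOfBeams = 2
    refbeams = []
    beams = []
    for number, gantry in ((1, 90.0), (2, 270.0)):
        beam = Dataset()
        beam.BeamNumber = number
        beam.BeamName = f"LAT{'L' if gantry == 90.0 else 'R'}"
        beam.BeamType = "STATIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentMachineName = "synthetic-linac"
        beam.SourceAxisDistance = 1000.0
        beam.NumberOfControlPoints = 2
        beam.FinalCumulativeMetersetWeight = 1.0

        bld_seq = []
        for dev_type, n in (("ASYMX", 1), ("ASYMY", 1), ("MLCX", n_leaf_pairs)):
            bld = Dataset()
            bld.RTBeamLimitingDeviceType = dev_type
            bld.NumberOfLeafJawPairs = n
            if dev_type == "MLCX":
                bld.LeafPositionBoundaries = _mlc_boundaries(n_leaf_pairs)
            bld_seq.append(bld)
        beam.BeamLimitingDeviceSequence = bld_seq

        cp0 = Dataset()
        cp0.ControlPointIndex = 0
        cp0.NominalBeamEnergy = 6.0
        cp0.GantryAngle = gantry
        cp0.GantryRotationDirection = "NONE"
        cp0.BeamLimitingDeviceAngle = 0.0
        cp0.PatientSupportAngle = 0.0
        cp0.IsocenterPosition = [float(v) for v in isocenter_mm]
        cp0.CumulativeMetersetWeight = 0.0
        pos_seq = []
        for dev_type, positions in (
            ("ASYMX", [-80.0, 80.0]),
            ("ASYMY", [-70.0, 70.0]),
            ("MLCX", [-60.0] * n_leaf_pairs + [60.0] * n_leaf_pairs),
        ):
            p = Dataset()
            p.RTBeamLimitingDeviceType = dev_type
            p.LeafJawPositions = positions
            pos_seq.append(p)
        cp0.BeamLimitingDevicePositionSequence = pos_seq
        cp1 = Dataset()
        cp1.ControlPointIndex = 1
        cp1.CumulativeMetersetWeight = 1.0
        beam.ControlPointSequence = [cp0, cp1]
        beams.append(beam)

        rb = Dataset()
        rb.ReferencedBeamNumber = number
        rb.BeamMeterset = 100.0
        refbeams.append(rb)
    fg.ReferencedBeamSequence = refbeams
    ds.FractionGroupSequence = [fg]
    ds.BeamSequence = beams
    return PlanTemplate(ds)


# ---------------------------------------------------------------------------
# Internal array+JSON format (fast path for tests and caching)
# ---------------------------------------------------------------------------

def _geom_to_dict(geom: ImageGeometry) -> dict:
    return {
        "spacing_mm": list(geom.spacing_mm),
        "origin_mm": list(geom.origin_mm),
        "axes": [list(a) for a in geom.axes],
    }


def _geom_from_dict(d: dict) -> ImageGeometry:
    return ImageGeometry(
        spacing_mm=tuple(d["spacing_mm"]),
        origin_mm=tuple(d["origin_mm"]),
        axes=tuple(tuple(a) for a in d["axes"]),
    )


def save_volume(ct: CTVolume, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(path, voxels=ct.voxels)
    path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    path.with_suffix(".json").write_text(
        json.dumps({"kind": "ct_volume", **_geom_to_dict(ct.geometry)}))
    return path


def load_volume(path: str | Path) -> CTVolume:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    voxels = np.load(path)["voxels"]
    return CTVolume(voxels, _geom_from_dict(header))


def save_structure_set_npz(ss: StructureSet, path: str | Path) -> Path:
    path = Path(path)
    np.savez_compressed(path, **{n: m.voxels for n, m in ss.masks.items()})
    path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    path.with_suffix(".json").write_text(json.dumps(
        {"kind": "structure_set", "names": ss.names(), **_geom_to_dict(ss.geometry)}))
    return path


def load_structure_set_npz(path: str | Path) -> StructureSet:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    geom = _geom_from_dict(header)
    with np.load(path) as data:
        masks = {n: BinaryMask(data[n], geom) for n in header["names"]}
    return StructureSet(masks)
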