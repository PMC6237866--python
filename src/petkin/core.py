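"""Core domain types and file I/O for the dynamic-PET pipeline.

Unit conventions, fixed package-wide:

* time   — minutes (seconds-denominated inputs are converted at the boundary)
* activity — kBq/mL for tissue, plasma and voxel values
* space  — world coordinates in mm via the NIfTI affine; voxel indices 0-based

Images travel as NIfTI-1 files; frame timing travels in a JSON sidecar next to
the image (NIfTI has no portable frame-timing field). Tables are CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    ContractError,
    MissingMetadataError,
    ParseError,
    ScheduleMismatchError,
    SchemaError,
)

#: Canonical TCI trait column names (Temperament and Character Inventory).
TCI_TRAITS = (
    "novelty_seeking",
    "harm_avoidance",
    "reward_dependence",
    "persistence",
    "self_directedness",
    "cooperativeness",
    "self_transcendence",
)

#: Region labels every atlas must provide. Thalamic subregions follow the
#: anterior-medial/anterior-lateral/central-medial/central-lateral/posterior
#: parcellation; SON is the supraoptic-nucleus locus of the right hypothalamus.
REQUIRED_REGIONS = (
    "cerebellum",
    "thalamus_AM",
    "thalamus_AL",
    "thalamus_CM",
    "thalamus_CL",
    "thalamus_P",
    "amygdala_L",
    "amygdala_R",
    "hypothalamus_L",
    "hypothalamus_R",
    "SON",
    "medulla",
)


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing in minutes.

    Frames must be contiguous, non-overlapping and strictly increasing.
    """

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or start.shape != end.shape:
            raise ContractError("frame_start and frame_end must be equal-length 1-D")
        if not np.all(end > start):
            raise ContractError("every frame must have positive duration")
        if not np.allclose(start[1:], end[:-1]):
            raise ContractError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return len(self.frame_start)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1] - self.frame_start[0])

    def to_dict(self) -> dict:
        return {
            "frame_start_min": self.frame_start.tolist(),
            "frame_end_min": self.frame_end.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FrameSchedule":
        return cls(np.asarray(d["frame_start_min"], dtype=float),
                   np.asarray(d["frame_end_min"], dtype=float))

    @classmethod
    def from_durations(cls, durations_min: Sequence[float], t0: float = 0.0) -> "FrameSchedule":
        end = t0 + np.cumsum(np.asarray(durations_min, dtype=float))
        start = np.concatenate([[t0], end[:-1]])
        return cls(start, end)


def make_study_schedule() -> FrameSchedule:
    """The study's 60-min dynamic acquisition: 6x10 s, 6x30 s, 11x60 s, 15x180 s."""
    durations_sec = [10.0] * 6 + [30.0] * 6 + [60.0] * 11 + [180.0] * 15
    return FrameSchedule.from_durations(np.asarray(durations_sec) / 60.0)


#: Arterial sampling times (minutes): every 10 s to 3 min, then sparser to 60 min.
ARTERIAL_SAMPLE_TIMES = np.concatenate([
    np.arange(10.0, 181.0, 10.0) / 60.0,
    np.array([4.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0]),
])

#: Venous sampling times (minutes).
VENOUS_SAMPLE_TIMES = np.array([5.0, 10.0, 20.0, 30.0, 45.0, 60.0])


@dataclass
class TimeActivityCurve:
    """Decay-corrected activity concentration versus time for one compartment.

    ``model``, when present, is the analytic generator of the curve (e.g. an
    :class:`~petkin.synthetic.AifParams`); downstream code exploits it for
    exact integrals instead of re-interpolating samples.
    """

    times: np.ndarray
    activity: np.ndarray
    label: str = ""
    model: object | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.times.shape != self.activity.shape or self.times.ndim != 1:
            raise ContractError("times and activity must be equal-length 1-D")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ContractError("times must be strictly increasing")
        if not np.all(np.isfinite(self.activity)):
            raise ContractError("activity must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DynamicImage:
    """4-D dynamic PET image: (x, y, z, frame) voxels in kBq/mL."""

    voxels: np.ndarray
    affine: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 4:
            raise ContractError("dynamic image must be 4-D")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ScheduleMismatchError(
                f"image has {self.voxels.shape[3]} frames but schedule has "
                f"{self.schedule.n_frames}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ContractError("affine must be invertible")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class VoiAtlas:
    """Labelled volume-of-interest image sharing the dynamic image's grid."""

    labels: np.ndarray
    affine: np.ndarray
    name_map: dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ContractError("atlas labels must be integer")
        names = list(self.name_map.values())
        if len(set(names)) != len(names):
            raise ContractError("name_map must be injective")
        present = set(np.unique(self.labels)) - {0}
        missing = {lab for lab in self.name_map if lab not in present}
        if missing:
            raise ContractError(f"labels named but absent from array: {sorted(missing)}")

    @property
    def label_of(self) -> dict[str, int]:
        return {v: k for k, v in self.name_map.items()}

    def mask(self, region: str) -> np.ndarray:
        """Boolean mask for a named region."""
        try:
            return self.labels == self.label_of[region]
        except KeyError:
            raise ContractError(f"region {region!r} not in atlas") from None

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class SubjectRecord:
    """One study participant: demographics and questionnaire scores."""

    id: str
    sex: str
    age: float
    baq_total: float
    tci: dict[str, float] = field(default_factory=dict)
    arterial_sampled: bool = False

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ParseError(f"sex must be 'F' or 'M', got {self.sex!r}")
        vals = [self.age, self.baq_total, *self.tci.values()]
        if not np.all(np.isfinite(vals)):
            raise ParseError(f"non-finite score for subject {self.id}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return p.with_name(name + ".json")


def write_dynamic_image(image: DynamicImage, path) -> None:
    """Write a 4-D NIfTI plus its frame-schedule JSON sidecar."""
    if np.isnan(image.voxels).any():
        warnings.warn("dynamic image contains NaN voxels; writing them as-is")
    nib.save(nib.Nifti1Image(image.voxels, image.affine), str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump({**image.schedule.to_dict(), "units": "kBq/mL"}, fh)


def read_dynamic_image(path) -> DynamicImage:
    """Read a 4-D NIfTI with its frame-schedule sidecar."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ContractError(f"expected 4-D image, got {data.ndim}-D")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MissingMetadataError(f"frame-schedule sidecar not found: {sidecar}")
    with open(sidecar) as fh:
        schedule = FrameSchedule.from_dict(json.load(fh))
    return DynamicImage(data, img.affine, schedule)


def write_atlas(atlas: VoiAtlas, path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine), str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump({str(k): v for k, v in atlas.name_map.items()}, fh)


def read_atlas(path) -> VoiAtlas:
    img = nib.load(str(path))
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MissingMetadataError(f"atlas label-name sidecar not found: {sidecar}")
    with open(sidecar) as fh:
        name_map = {int(k): v for k, v in json.load(fh).items()}
    return VoiAtlas(np.asarray(img.dataobj).astype(np.int32), img.affine, name_map)


COHORT_COLUMNS = ("id", "sex", "age", "baq_total") + tuple(
    f"tci_{t}" for t in TCI_TRAITS) + ("arterial_sampled",)


def read_cohort_table(path) -> list[SubjectRecord]:
    """Read the per-subject covariate CSV into SubjectRecord objects."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cohort table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        try:
            tci = {t: float(row[f"tci_{t}"]) for t in TCI_TRAITS}
            rec = SubjectRecord(
                id=str(row["id"]), sex=str(row["sex"]), age=float(row["age"]),
                baq_total=float(row["baq_total"]), tci=tci,
                arterial_sampled=bool(row["arterial_sampled"]))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"bad row for subject {row['id']!r}: {exc}") from exc
        records.append(rec)
    return records


def write_cohort_table(records: Sequence[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        row = {"id": r.id, "sex": r.sex, "age": r.age, "baq_total": r.baq_total}
        row.update({f"tci_{t}": r.tci[t] for t in TCI_TRAITS})
        row["arterial_sampled"] = r.arterial_sampled
        rows.append(row)
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def write_tac_csv(tac: TimeActivityCurve, path) -> None:
    pd.DataFrame({"time_min": tac.times, "activity_kBq_mL": tac.activity}).to_csv(
        path, index=False)


def read_tac_csv(path, label: str = "") -> TimeActivityCurve:
    df = pd.read_csv(path)
    if not {"time_min", "activity_kBq_mL"} <= set(df.columns):
        raise SchemaError("TAC CSV needs columns time_min, activity_kBq_mL")
    return TimeActivityCurve(df["time_min"].to_numpy(), df["activity_kBq_mL"].to_numpy(),
                             label=label)
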