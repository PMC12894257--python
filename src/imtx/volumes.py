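"""Voxel-lattice data model, NIfTI / peak-table I/O, and statistic conversions.

Every map-valued object in the pipeline lives on a :class:`VolumeGrid`: a
regular voxel lattice with a 4x4 voxel-to-world (MNI mm, RAS+) affine and a
boolean gray-matter analysis mask.  Peak tables carry reported group-contrast
maxima (t, z or p statistics, MNI or Talairach coordinates) for each study
entering the coordinate-based meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VolumeGrid",
    "StatMap",
    "PeakRecord",
    "Study",
    "StudySet",
    "PeakTableFormatError",
    "SmallSampleError",
    "MNI_BOUNDS",
    "read_peak_table",
    "write_peak_table",
    "tal_to_mni",
    "convert_stat",
    "peak_to_t",
    "read_stat_map",
    "write_stat_map",
    "read_mask",
    "write_mask",
]

STAT_KINDS = ("t", "z", "d", "p")

#: MNI bounding box (mm) spanned by the default grid, per axis: x, y, z.
MNI_BOUNDS = ((-90.0, 90.0), (-126.0, 90.0), (-72.0, 108.0))

# Lancaster icbm_spm2tal affine; the Talairach->MNI conversion applies its
# inverse.  A single fixed affine (not the piecewise variant) — approximate,
# adequate for peak tables whose coordinates are themselves approximate.
_ICBM_SPM2TAL = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
_TAL2MNI = np.linalg.inv(_ICBM_SPM2TAL)


class PeakTableFormatError(ValueError):
    """Raised when a peak table is missing columns or carries invalid values."""


class SmallSampleError(ValueError):
    """Raised when a study violates the small-sample inclusion rule (n <= 7)."""


class VolumeGrid:
    """Regular voxel lattice with affine and gray-matter mask.

    Parameters
    ----------
    dims:
        Number of voxels along each axis.
    affine:
        4x4 voxel-index -> world (mm) transform; must be invertible.
    mask:
        Boolean array of shape ``dims`` with at least one True voxel.
    """

    def __init__(self, dims: Sequence[int], affine: np.ndarray, mask: np.ndarray):
        self.dims = tuple(int(d) for d in dims)
        self.affine = np.asarray(affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.dims:
            raise ValueError(f"mask shape {mask.shape} does not match dims {self.dims}")
        if not mask.any():
            raise ValueError("mask must contain at least one voxel")
        self.mask = mask
        self._inv_affine = np.linalg.inv(self.affine)
        self._mask_world: np.ndarray | None = None

    @classmethod
    def mni(cls, voxel_size: float = 2.0, mask: np.ndarray | None = None) -> "VolumeGrid":
        """Isotropic lattice over the MNI bounding box (RAS+, 0-based indices)."""
        dims = tuple(
            int(np.floor((hi - lo) / voxel_size)) + 1 for lo, hi in MNI_BOUNDS
        )
        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        affine[:3, 3] = [lo for lo, _ in MNI_BOUNDS]
        if mask is None:
            mask = np.ones(dims, dtype=bool)
        return cls(dims, affine, mask)

    @property
    def voxel_size(self) -> np.ndarray:
        """Physical voxel extent (mm) per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_mask(self) -> int:
        return int(self.mask.sum())

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz if xyz.shape[0] > 1 else xyz[0]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        ijk = xyz @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]
        return ijk if ijk.shape[0] > 1 else ijk[0]

    def nearest_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Index of the voxel whose center is nearest to ``xyz`` (rounded)."""
        return np.rint(self.world_to_voxel(xyz)).astype(int)

    def in_bounds(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        ok = np.ones(ijk.shape[0], dtype=bool)
        for ax in range(3):
            ok &= (ijk[:, ax] >= 0) & (ijk[:, ax] < self.dims[ax])
        return ok if len(ok) > 1 else ok[:1]

    def mask_world_coords(self) -> np.ndarray:
        """World coordinates (mm) of every in-mask voxel center, C-ordered."""
        if self._mask_world is None:
            ijk = np.argwhere(self.mask)
            self._mask_world = np.atleast_2d(self.voxel_to_world(ijk))
        return self._mask_world

    def matches(self, other: "VolumeGrid") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.affine, other.affine)
            and np.array_equal(self.mask, other.mask)
        )


@dataclass
class StatMap:
    """Scalar statistic sampled on a :class:`VolumeGrid`.

    ``data`` holds the full lattice; values are only meaningful inside
    ``grid.mask`` (and must be finite there).
    """

    grid: VolumeGrid
    data: np.ndarray
    kind: str = "t"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.dims:
            raise ValueError("data shape does not match grid dims")
        if self.kind not in STAT_KINDS:
            raise ValueError(f"kind must be one of {STAT_KINDS}")
        if not np.isfinite(self.data[self.grid.mask]).all():
            raise ValueError("non-finite values inside the analysis mask")

    @property
    def values(self) -> np.ndarray:
        """In-mask values, C-ordered (matches ``grid.mask_world_coords()``)."""
        return self.data[self.grid.mask]

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "StatMap":
        """New map on the same grid from a vector of in-mask values."""
        data = np.zeros(self.grid.dims)
        data[self.grid.mask] = values
        return StatMap(self.grid, data, kind or self.kind)


@dataclass
class PeakRecord:
    """A reported local maximum of a group contrast."""

    xyz: np.ndarray
    stat_value: float
    stat_kind: str = "t"
    space: str = "MNI"
    sign: str = "increase"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.isfinite(self.xyz).all():
            raise ValueError("xyz must be a finite 3-vector")
        if self.stat_kind not in ("t", "z", "p"):
            raise ValueError("stat_kind must be one of t, z, p")
        if self.space not in ("MNI", "Talairach"):
            raise ValueError("space must be MNI or Talairach")
        if self.sign not in ("increase", "decrease"):
            raise ValueError("sign must be increase or decrease")
        if self.stat_kind == "p" and not (0.0 < self.stat_value <= 1.0):
            raise PeakTableFormatError(
                f"p-value peak statistic must lie in (0, 1], got {self.stat_value}"
            )


@dataclass
class Study:
    id: str
    n_patients: int
    n_controls: int
    peaks: list[PeakRecord] = field(default_factory=list)
    mean_age: float | None = None
    illness_duration: float | None = None

    @property
    def df(self) -> int:
        return self.n_patients + self.n_controls - 2


@dataclass
class StudySet:
    studies: list[Study]

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("StudySet requires at least one study")
        for s in self.studies:
            if s.n_patients <= 7 or s.n_controls <= 7:
                raise SmallSampleError(
                    f"study {s.id!r}: groups with seven or fewer individuals are "
                    f"excluded (n_patients={s.n_patients}, n_controls={s.n_controls})"
                )

    def __iter__(self):
        return iter(self.studies)

    def __len__(self) -> int:
        return len(self.studies)

    @property
    def n_peaks(self) -> int:
        return sum(len(s.peaks) for s in self.studies)


# ---------------------------------------------------------------------------
# coordinate and statistic conversions


def tal_to_mni(xyz: Sequence[float]) -> np.ndarray:
    """Talairach mm -> MNI mm via the inverse Lancaster icbm2tal affine."""
    xyz = np.asarray(xyz, dtype=float)
    out = _TAL2MNI[:3, :3] @ xyz + _TAL2MNI[:3, 3]
    return out


def mni_to_tal(xyz: Sequence[float]) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    return _ICBM_SPM2TAL[:3, :3] @ xyz + _ICBM_SPM2TAL[:3, 3]


def convert_stat(
    value: float, from_kind: str, df: int | None = None, sign: int = 1
) -> float:
    """Convert a reported peak statistic to a (signed) two-sample t-value.

    z converts by quantile matching (t quantile at the standard-normal CDF of
    z); a two-tailed p converts through the t inverse survival function with
    the sign taken from ``sign``.  t passes through.
    """
    if from_kind == "t":
        return float(value)
    if df is None or df < 1:
        raise ValueError("df is required to convert z or p statistics to t")
    if from_kind == "z":
        # symmetric quantile matching; mirror negative z for tail accuracy
        if value >= 0:
            return float(stats.t.isf(stats.norm.sf(value), df))
        return float(-stats.t.isf(stats.norm.sf(-value), df))
    if from_kind == "p":
        if not (0.0 < value <= 1.0):
            raise ValueError("two-tailed p must lie in (0, 1]")
        return float(np.sign(sign) * stats.t.isf(value / 2.0, df))
    raise ValueError(f"unknown statistic kind {from_kind!r}")


def peak_to_t(peak: PeakRecord, df: int) -> float:
    """Signed t-value of a peak; the sign field is authoritative."""
    sgn = 1 if peak.sign == "increase" else -1
    if peak.stat_kind == "p":
        return convert_stat(peak.stat_value, "p", df, sign=sgn)
    t = convert_stat(peak.stat_value, peak.stat_kind, df)
    return sgn * abs(t)


def peak_xyz_mni(peak: PeakRecord) -> np.ndarray:
    """Peak coordinates in MNI mm (Talairach peaks converted)."""
    if peak.space == "Talairach":
        return tal_to_mni(peak.xyz)
    return np.asarray(peak.xyz, dtype=float)


# ---------------------------------------------------------------------------
# peak-table I/O

_REQUIRED_COLUMNS = (
    "study",
    "n_patients",
    "n_controls",
    "x",
    "y",
    "z",
    "stat",
    "stat_kind",
    "space",
    "sign",
)


def read_peak_table(path: str | Path) -> StudySet:
    """Parse a delimited peak table (one row per reported peak) into a StudySet.

    Raises
    ------
    PeakTableFormatError
        If a required column is absent or a statistic is out of range.
    SmallSampleError
        If any study has seven or fewer individuals in either group.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(
            f"peak table {path} is missing required column(s): {', '.join(missing)}"
        )
    studies: list[Study] = []
    for sid, rows in df.groupby("study", sort=False):
        n_pat = int(rows["n_patients"].iloc[0])
        n_con = int(rows["n_controls"].iloc[0])
        peaks = [
            PeakRecord(
                xyz=np.array([r.x, r.y, r.z], dtype=float),
                stat_value=float(r.stat),
                stat_kind=str(r.stat_kind),
                space=str(r.space),
                sign=str(r.sign),
            )
            for r in rows.itertuples()
        ]
        mean_age = (
            float(rows["mean_age"].iloc[0])
            if "mean_age" in rows and pd.notna(rows["mean_age"].iloc[0])
            else None
        )
        dur = (
            float(rows["illness_duration"].iloc[0])
            if "illness_duration" in rows and pd.notna(rows["illness_duration"].iloc[0])
            else None
        )
        studies.append(
            Study(str(sid), n_pat, n_con, peaks, mean_age=mean_age, illness_duration=dur)
        )
    return StudySet(studies)


def write_peak_table(study_set: StudySet, path: str | Path) -> None:
    rows = []
    for s in study_set:
        for p in s.peaks:
            rows.append(
                {
                    "study": s.id,
                    "n_patients": s.n_patients,
                    "n_controls": s.n_controls,
                    "x": p.xyz[0],
                    "y": p.xyz[1],
                    "z": p.xyz[2],
                    "stat": p.stat_value,
                    "stat_kind": p.stat_kind,
                    "space": p.space,
                    "sign": p.sign,
                    "mean_age": s.mean_age,
                    "illness_duration": s.illness_duration,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_stat_map(smap: StatMap, path: str | Path) -> None:
    """Write a map as NIfTI-1 (float64 payload; affine preserved exactly)."""
    img = nib.Nifti1Image(smap.data.astype(np.float64), smap.grid.affine)
    nib.save(img, str(path))


def read_stat_map(
    path: str | Path, grid: VolumeGrid | None = None, kind: str = "t"
) -> StatMap:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if grid is not None:
        if tuple(data.shape) != grid.dims or not np.allclose(img.affine, grid.affine):
            raise ValueError(
                f"volume {path} (shape {data.shape}) does not match the expected "
                f"grid {grid.dims}"
            )
    else:
        grid = VolumeGrid(data.shape, img.affine, np.ones(data.shape, dtype=bool))
    data[~grid.mask] = 0.0
    return StatMap(grid, data, kind)


def write_mask(grid: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(grid.mask.astype(np.uint8), grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    mask = np.asarray(img.get_fdata()) > 0.5
    return VolumeGrid(mask.shape, img.affine, mask)
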