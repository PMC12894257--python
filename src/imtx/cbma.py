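"""Coordinate-based meta-analysis of gray-matter peak tables.

Per-study signed effect-size maps are reconstructed from reported peaks with
an isotropic Gaussian kernel at a stated FWHM, pooled voxel-wise with a
DerSimonian-Laird random-effects model, and thresholded against a
peak-relocation permutation null.  Robustness diagnostics follow the
standard battery: leave-one-study-out jackknife, Cochran-Q heterogeneity
mapping, and Egger regression with funnel-point export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import ndimage, stats

from .volumes import StatMap, Study, StudySet, VolumeGrid, peak_to_t, peak_xyz_mni

logger = logging.getLogger(__name__)

__all__ = [
    "reconstruct_effect_map",
    "pool_random_effects",
    "build_relocation_null",
    "threshold_and_cluster",
    "heterogeneity_clusters",
    "jackknife",
    "egger_and_funnel",
    "meta_analysis",
    "PooledResult",
    "ClusterRecord",
    "MetaResult",
]

_CONN26 = np.ones((3, 3, 3), dtype=int)


def hedges_g(t: float, n1: int, n2: int) -> float:
    """Small-sample-corrected standardized mean difference from a t-value."""
    df = n1 + n2 - 2
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return j * t * np.sqrt(1.0 / n1 + 1.0 / n2)


def g_variance(g: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Standard variance of Hedges g: (n1+n2)/(n1*n2) + g^2/(2*(n1+n2))."""
    n = n1 + n2
    return (n / (n1 * n2)) + np.square(g) / (2.0 * n)


# ---------------------------------------------------------------------------
# per-study map reconstruction

_kernel_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _kernel_offsets(grid: VolumeGrid, fwhm: float) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-index offsets within the truncation radius (2*FWHM) and their
    world-space displacement vectors, cached per (voxel size, fwhm)."""
    key = (tuple(np.round(grid.voxel_size, 6)), float(fwhm))
    if key not in _kernel_cache:
        radius = 2.0 * fwhm
        nvox = np.ceil(radius / grid.voxel_size).astype(int)
        rng_ = [np.arange(-n, n + 1) for n in nvox]
        offs = np.stack(np.meshgrid(*rng_, indexing="ij"), axis=-1).reshape(-1, 3)
        world = offs @ grid.affine[:3, :3].T
        keep = np.linalg.norm(world, axis=1) <= radius + np.max(grid.voxel_size)
        _kernel_cache[key] = (offs[keep], world[keep])
    return _kernel_cache[key]


def _study_effect_arrays(
    peaks_xyz: np.ndarray,
    peaks_g: np.ndarray,
    n1: int,
    n2: int,
    grid: VolumeGrid,
    fwhm: float,
    combine: str = "max",
) -> tuple[np.ndarray, np.ndarray]:
    """Full-lattice (d, v) arrays for one study given converted peaks."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    radius = 2.0 * fwhm
    d = np.zeros(grid.dims)
    offs, world_offs = _kernel_offsets(grid, fwhm)
    for xyz, g in zip(peaks_xyz, peaks_g):
        center = grid.nearest_voxel(xyz)
        idx = offs + center
        ok = (
            (idx[:, 0] >= 0) & (idx[:, 0] < grid.dims[0])
            & (idx[:, 1] >= 0) & (idx[:, 1] < grid.dims[1])
            & (idx[:, 2] >= 0) & (idx[:, 2] < grid.dims[2])
        )
        idx = idx[ok]
        center_world = grid.voxel_to_world(center)
        disp = world_offs[ok] + (center_world - xyz)
        r2 = np.einsum("ij,ij->i", disp, disp)
        inside = r2 <= radius**2
        idx = idx[inside]
        contrib = g * np.exp(-r2[inside] / (2.0 * sigma**2))
        cur = d[idx[:, 0], idx[:, 1], idx[:, 2]]
        if combine == "max":
            take = np.abs(contrib) > np.abs(cur)
            new = np.where(take, contrib, cur)
        elif combine == "sum":
            new = cur + contrib
        else:
            raise ValueError("combine must be 'max' or 'sum'")
        d[idx[:, 0], idx[:, 1], idx[:, 2]] = new
    v = g_variance(d, n1, n2)
    return d, v


def _study_peaks(study: Study) -> tuple[np.ndarray, np.ndarray]:
    """MNI coordinates and Hedges-g values of a study's usable peaks."""
    xyz, gs = [], []
    for p in study.peaks:
        t = peak_to_t(p, study.df)
        xyz.append(peak_xyz_mni(p))
        gs.append(hedges_g(t, study.n_patients, study.n_controls))
    if not xyz:
        return np.zeros((0, 3)), np.zeros(0)
    return np.asarray(xyz), np.asarray(gs)


def reconstruct_effect_map(
    study: Study, grid: VolumeGrid, fwhm: float = 20.0, combine: str = "max"
) -> tuple[StatMap, StatMap]:
    """Signed effect-size (d) and variance maps for one study.

    Each peak statistic converts to small-sample-corrected Hedges g; a voxel
    takes the kernel-weighted contribution of the nearest-in-magnitude peak
    (signed maximum-magnitude combination by default), with the Gaussian
    kernel truncated at twice its FWHM.  A study without usable peaks yields
    a flat zero map (a valid null study).
    """
    xyz, gs = _study_peaks(study)
    if len(gs) == 0:
        logger.warning("study %s has no usable peaks; flat zero map", study.id)
    d, v = _study_effect_arrays(xyz, gs, study.n_patients, study.n_controls, grid, fwhm, combine)
    zero = np.zeros(grid.dims)
    d_data, v_data = zero.copy(), zero.copy()
    d_data[grid.mask] = d[grid.mask]
    v_data[grid.mask] = v[grid.mask]
    return StatMap(grid, d_data, "d"), StatMap(grid, v_data, "d")


# ---------------------------------------------------------------------------
# random-effects pooling


@dataclass
class PooledResult:
    z_map: StatMap
    mean: np.ndarray  # pooled g per in-mask voxel
    se: np.ndarray
    tau2: np.ndarray
    Q: np.ndarray
    k: int

    @property
    def z(self) -> np.ndarray:
        return self.z_map.values


def _pool_arrays(d: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, ...]:
    """DerSimonian-Laird pooling over axis 0 (studies x voxels)."""
    w = 1.0 / v
    sw = w.sum(axis=0)
    dbar = (w * d).sum(axis=0) / sw
    Q = (w * np.square(d - dbar)).sum(axis=0)
    k = d.shape[0]
    c = sw - (w**2).sum(axis=0) / sw
    tau2 = np.clip((Q - (k - 1)) / c, 0.0, None)
    wstar = 1.0 / (v + tau2)
    mean = (wstar * d).sum(axis=0) / wstar.sum(axis=0)
    se = np.sqrt(1.0 / wstar.sum(axis=0))
    return mean, se, tau2, Q


def pool_random_effects(
    maps: list[tuple[StatMap, StatMap]], grid: VolumeGrid | None = None
) -> PooledResult:
    """Voxel-wise DerSimonian-Laird random-effects pooling of study maps.

    Weights are 1/(v_i + tau^2) with tau^2 from the Q statistic truncated at
    zero; the output z map is pooled mean over its standard error.
    """
    if not maps:
        raise ValueError("no study maps to pool")
    grid = grid or maps[0][0].grid
    d = np.stack([m.values for m, _ in maps])
    v = np.stack([vm.values for _, vm in maps])
    if len(maps) == 1:
        logger.warning("single study: pooled map degenerates to that study")
        mean, se = d[0], np.sqrt(v[0])
        tau2 = np.zeros_like(mean)
        Q = np.zeros_like(mean)
    else:
        mean, se, tau2, Q = _pool_arrays(d, v)
    z = mean / se
    data = np.zeros(grid.dims)
    data[grid.mask] = z
    return PooledResult(StatMap(grid, data, "z"), mean, se, tau2, Q, k=d.shape[0])


# ---------------------------------------------------------------------------
# permutation null and thresholding


def build_relocation_null(
    study_set: StudySet,
    grid: VolumeGrid,
    fwhm: float = 20.0,
    n_iter: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    combine: str = "max",
) -> np.ndarray:
    """Pooled null |z| values from uniform peak relocation within the mask.

    Each iteration relocates every study's peaks to uniformly drawn in-mask
    voxel centers (keeping their effect sizes), re-pools, and contributes the
    full in-mask |z| vector to a single pooled null distribution.
    """
    if n_iter < 1:
        raise ValueError("empty null ensemble")
    rng = rng if rng is not None else np.random.default_rng(seed)
    coords = grid.mask_world_coords()
    peak_info = [_study_peaks(s) + (s.n_patients, s.n_controls) for s in study_set]
    null_vals = np.empty((n_iter, grid.n_mask))
    for it in range(n_iter):
        d_stack, v_stack = [], []
        for xyz, gs, n1, n2 in peak_info:
            new_xyz = coords[rng.integers(coords.shape[0], size=len(gs))]
            d, v = _study_effect_arrays(new_xyz, gs, n1, n2, grid, fwhm, combine)
            d_stack.append(d[grid.mask])
            v_stack.append(v[grid.mask])
        if len(d_stack) == 1:
            mean, se = d_stack[0], np.sqrt(v_stack[0])
        else:
            mean, se, _, _ = _pool_arrays(np.stack(d_stack), np.stack(v_stack))
        null_vals[it] = np.abs(mean / se)
    return np.sort(null_vals.ravel())


@dataclass
class ClusterRecord:
    peak_xyz: np.ndarray
    peak_z: float
    extent: int
    sign: str
    p_peak: float
    voxels: np.ndarray  # (n, 3) voxel indices
    egger_p: float | None = None
    jackknife: str | None = None
    heterogeneous: bool | None = None
    funnel: list[tuple[float, float]] = field(default_factory=list)


def _clusters_from_binary(
    binary: np.ndarray, zdata: np.ndarray, grid: VolumeGrid, sign: str,
    peak_z: float, extent: int, p_full: np.ndarray,
) -> list[ClusterRecord]:
    labels, n = ndimage.label(binary, structure=_CONN26)
    out = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < extent:
            continue
        zvals = zdata[vox[:, 0], vox[:, 1], vox[:, 2]]
        i_peak = int(np.argmax(np.abs(zvals)))
        if abs(zvals[i_peak]) < peak_z:
            continue
        peak_ijk = vox[i_peak]
        out.append(
            ClusterRecord(
                peak_xyz=np.asarray(grid.voxel_to_world(peak_ijk), dtype=float),
                peak_z=float(zvals[i_peak]),
                extent=int(len(vox)),
                sign=sign,
                p_peak=float(p_full[peak_ijk[0], peak_ijk[1], peak_ijk[2]]),
                voxels=vox,
            )
        )
    out.sort(key=lambda c: -abs(c.peak_z))
    return out


def threshold_and_cluster(
    pooled: PooledResult,
    null_abs_z: np.ndarray,
    voxel_p: float = 0.005,
    peak_z: float = 1.0,
    extent: int = 50,
) -> tuple[list[ClusterRecord], StatMap]:
    """Voxel p from the pooled relocation null; signed 26-connected clusters.

    A voxel's p is the add-one rank of its |z| in the pooled null values.
    Suprathreshold voxels are clustered separately for increases and
    decreases; clusters survive if their peak |z| >= ``peak_z`` and their
    extent >= ``extent`` voxels.
    """
    if null_abs_z.size == 0:
        raise ValueError("empty null ensemble")
    grid = pooled.z_map.grid
    z = pooled.z
    n_null = null_abs_z.size
    # rank of |z| among sorted null values (add-one permutation convention)
    n_ge = n_null - np.searchsorted(null_abs_z, np.abs(z), side="left")
    p = (1.0 + n_ge) / (n_null + 1.0)
    p_full = np.ones(grid.dims)
    p_full[grid.mask] = p
    supra = np.zeros(grid.dims, dtype=bool)
    supra[grid.mask] = p < voxel_p
    zdata = pooled.z_map.data
    clusters = _clusters_from_binary(
        supra & (zdata > 0), zdata, grid, "increase", peak_z, extent, p_full
    ) + _clusters_from_binary(
        supra & (zdata < 0), zdata, grid, "decrease", peak_z, extent, p_full
    )
    return clusters, StatMap(grid, p_full, "p")


def heterogeneity_clusters(
    pooled: PooledResult,
    voxel_p: float = 0.005,
    peak_z: float = 1.0,
    extent: int = 10,
) -> list[ClusterRecord]:
    """Cochran-Q heterogeneity map thresholded and clustered.

    Q is referred to chi-square with k-1 degrees of freedom; the p-value is
    expressed as an equivalent normal z for the peak-height rule.  Note the
    smaller extent threshold relative to the main analysis.
    """
    grid = pooled.z_map.grid
    p = stats.chi2.sf(pooled.Q, pooled.k - 1)
    zq = stats.norm.isf(np.clip(p, 1e-300, 1.0))
    p_full = np.ones(grid.dims)
    p_full[grid.mask] = p
    zdata = np.zeros(grid.dims)
    zdata[grid.mask] = zq
    binary = np.zeros(grid.dims, dtype=bool)
    binary[grid.mask] = p < voxel_p
    return _clusters_from_binary(binary, zdata, grid, "heterogeneity", peak_z, extent, p_full)


# ---------------------------------------------------------------------------
# diagnostics


def _threshold_from_null(null_abs_z: np.ndarray, voxel_p: float) -> float:
    """|z| cutoff whose add-one permutation p falls below voxel_p."""
    n = null_abs_z.size
    # need (1 + n_ge)/(n+1) < voxel_p  =>  n_ge < voxel_p*(n+1) - 1
    k = int(np.ceil(voxel_p * (n + 1) - 1)) - 1  # largest allowed n_ge
    k = max(k, 0)
    return float(null_abs_z[n - k - 1])


def jackknife(
    study_maps: list[tuple[StatMap, StatMap]],
    main_clusters: list[ClusterRecord],
    null_abs_z: np.ndarray,
    voxel_p: float = 0.005,
    peak_z: float = 1.0,
    extent: int = 50,
) -> list[str]:
    """Leave-one-study-out survival of each main-analysis cluster.

    Each jackknife run re-pools the remaining maps and re-applies the main
    thresholds (reusing the full-sample relocation null).  A cluster survives
    a run if any same-sign surviving cluster overlaps its voxel set.  Returns
    "k/n" strings in main-cluster order.
    """
    if len(study_maps) < 3:
        raise ValueError("jackknife requires at least three studies")
    n = len(study_maps)
    survival = [0] * len(main_clusters)
    for leave in range(n):
        subset = [m for i, m in enumerate(study_maps) if i != leave]
        pooled = pool_random_effects(subset)
        clusters, _ = threshold_and_cluster(pooled, null_abs_z, voxel_p, peak_z, extent)
        for ci, main in enumerate(main_clusters):
            main_set = set(map(tuple, main.voxels))
            for c in clusters:
                if c.sign != main.sign:
                    continue
                if main_set.intersection(map(tuple, c.voxels)):
                    survival[ci] += 1
                    break
    return [f"{s}/{n}" for s in survival]


def egger_and_funnel(
    d_at_peak: np.ndarray, v_at_peak: np.ndarray
) -> tuple[float | None, float | None, list[tuple[float, float]]]:
    """Egger regression of standardized effect on precision at a cluster peak.

    Regresses d/SE on 1/SE across contributing studies (those with nonzero
    reconstructed effect); returns the intercept, its two-sided p, and the
    (effect, SE) funnel points.  With fewer than three contributing studies
    the test is undefined and reported as missing.
    """
    keep = d_at_peak != 0.0
    d, v = d_at_peak[keep], v_at_peak[keep]
    se = np.sqrt(v)
    funnel = list(zip(d_at_peak.tolist(), np.sqrt(v_at_peak).tolist()))
    if keep.sum() < 3:
        return None, None, funnel
    X = sm.add_constant(1.0 / se)
    fit = sm.OLS(d / se, X).fit()
    return float(fit.params[0]), float(fit.pvalues[0]), funnel


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class MetaResult:
    pooled: PooledResult
    p_map: StatMap
    clusters: list[ClusterRecord]
    heterogeneity: list[ClusterRecord]
    null_abs_z: np.ndarray
    study_maps: list[tuple[StatMap, StatMap]]

    @property
    def z_map(self) -> StatMap:
        return self.pooled.z_map

    def cluster_table(self):
        import pandas as pd

        het_sets = [set(map(tuple, h.voxels)) for h in self.heterogeneity]
        rows = []
        for c in self.clusters:
            cset = set(map(tuple, c.voxels))
            rows.append(
                {
                    "x": c.peak_xyz[0],
                    "y": c.peak_xyz[1],
                    "z": c.peak_xyz[2],
                    "extent": c.extent,
                    "peak_z": c.peak_z,
                    "p": c.p_peak,
                    "sign": c.sign,
                    "heterogeneity": any(cset & h for h in het_sets),
                    "egger_p": c.egger_p,
                    "jackknife": c.jackknife,
                }
            )
        return pd.DataFrame(rows)


def meta_analysis(
    study_set: StudySet,
    grid: VolumeGrid,
    fwhm: float = 20.0,
    voxel_p: float = 0.005,
    peak_z: float = 1.0,
    extent: int = 50,
    het_extent: int = 10,
    n_null: int = 200,
    seed: int | None = None,
    combine: str = "max",
    diagnostics: bool = True,
) -> MetaResult:
    """Full CBMA: reconstruction, pooling, thresholding, and diagnostics."""
    study_maps = [reconstruct_effect_map(s, grid, fwhm, combine) for s in study_set]
    pooled = pool_random_effects(study_maps, grid)
    null_abs_z = build_relocation_null(
        study_set, grid, fwhm, n_iter=n_null, seed=seed, combine=combine
    )
    clusters, p_map = threshold_and_cluster(pooled, null_abs_z, voxel_p, peak_z, extent)
    het = heterogeneity_clusters(pooled, voxel_p, peak_z, het_extent)
    if diagnostics and clusters:
        if len(study_set) >= 3:
            jk = jackknife(study_maps, clusters, null_abs_z, voxel_p, peak_z, extent)
        else:
            jk = [None] * len(clusters)
        for c, surv in zip(clusters, jk):
            peak_ijk = pooled.z_map.grid.nearest_voxel(c.peak_xyz)
            d_pk = np.array([m.data[tuple(peak_ijk)] for m, _ in study_maps])
            v_pk = np.array([vm.data[tuple(peak_ijk)] for _, vm in study_maps])
            intercept, p_eg, funnel = egger_and_funnel(d_pk, v_pk)
            c.egger_p = p_eg
            c.funnel = funnel
            c.jackknife = surv
    return MetaResult(pooled, p_map, clusters, het, null_abs_z, study_maps)
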