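"""Expression-atlas preprocessing: probe filtering and selection, scaled
robust sigmoid normalization, differential-stability gene filtering, and
gray-matter-mask restriction of samples.

The stage order is fixed: background-intensity filter -> RNA-seq-guided
probe selection -> SRS normalization (within-sample then within-gene) ->
differential-stability filter -> mask restriction.  Every filter logs its
before/after counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.vq import kmeans2

from .synth import AtlasBundle
from .volumes import VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "filter_probes_by_intensity",
    "select_probe_per_gene",
    "srs_normalize",
    "spatial_parcels",
    "differential_stability",
    "filter_top_fraction",
    "restrict_to_mask",
    "preprocess_atlas",
    "SampleGeneMatrix",
]


@dataclass
class SampleGeneMatrix:
    """Normalized samples-by-genes matrix with sample metadata and per-gene
    differential-stability values.  All values lie in [0, 1]; all retained
    samples fall inside the analysis mask."""

    data: pd.DataFrame  # samples x genes, [0, 1]
    meta: pd.DataFrame  # sample_id, donor, x, y, z (index aligned with data)
    ds: pd.Series  # per retained gene

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("normalized matrix contains missing values")
        v = self.data.to_numpy()
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("normalized values must lie in [0, 1]")


def filter_probes_by_intensity(
    expression: pd.DataFrame,
    above_background: pd.DataFrame,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Keep probes above background noise in at least ``min_fraction`` of
    samples across the full donor cohort."""
    frac = above_background.loc[expression.index].mean(axis=1)
    kept = expression.loc[frac >= min_fraction]
    logger.info("intensity filter: %d -> %d probes", len(expression), len(kept))
    return kept


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of two equal-shape matrices."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((az**2).sum(axis=1) * (bz**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az * bz).sum(axis=1) / denom
    return np.where(np.isfinite(r), r, 0.0)


def select_probe_per_gene(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    rnaseq: pd.DataFrame | None,
    min_r: float = 0.2,
) -> pd.DataFrame:
    """One representative probe per gene, guided by an RNA-seq reference.

    Each probe is correlated (Pearson, over shared samples) with its gene's
    RNA-seq profile; probes with r below ``min_r`` are excluded and the
    maximum-r survivor represents the gene.  Genes absent from the RNA-seq
    reference, or with no surviving probe, are dropped.  Without a reference
    the maximum-variance probe is used as a fallback (with a loud warning,
    since the correlation rule cannot run).
    """
    ann = annotation.set_index("probe_id")["gene"]
    ann = ann.loc[ann.index.intersection(expression.index)]
    if rnaseq is None:
        logger.warning(
            "no RNA-seq reference: falling back to maximum-variance probe selection"
        )
        var = expression.var(axis=1)
        best = (
            pd.DataFrame({"gene": ann, "score": var.loc[ann.index]})
            .sort_values(["gene", "score"], ascending=[True, False])
            .groupby("gene", sort=True)
            .head(1)
        )
    else:
        shared = expression.columns.intersection(rnaseq.columns)
        usable = ann[ann.isin(rnaseq.index)]
        probes = usable.index.to_numpy()
        a = expression.loc[probes, shared].to_numpy()
        b = rnaseq.loc[usable.to_numpy(), shared].to_numpy()
        r = _rowwise_pearson(a, b)
        cand = pd.DataFrame({"gene": usable.to_numpy(), "score": r}, index=probes)
        cand = cand[cand["score"] >= min_r]
        best = (
            cand.sort_values(["gene", "score"], ascending=[True, False])
            .groupby("gene", sort=True)
            .head(1)
        )
    out = expression.loc[best.index]
    out.index = pd.Index(best["gene"].to_numpy(), name="gene")
    out = out.sort_index()
    logger.info(
        "probe selection: %d probes -> %d genes", len(expression), len(out)
    )
    return out


def _srs_vector(x: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid of one vector: median/IQR sigmoid then min-max.

    IQR/1.35 approximates the SD under normality.  Zero-IQR vectors map to a
    constant 0.5.
    """
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        return np.full_like(x, 0.5, dtype=float)
    arg = np.clip(-(x - np.median(x)) / (iqr / 1.35), -700.0, 700.0)
    y = 1.0 / (1.0 + np.exp(arg))
    lo, hi = y.min(), y.max()
    if hi == lo:
        return np.full_like(x, 0.5, dtype=float)
    return (y - lo) / (hi - lo)


def srs_normalize(
    gene_by_sample: pd.DataFrame, order: tuple[str, str] = ("sample", "gene")
) -> pd.DataFrame:
    """Scaled-robust-sigmoid normalization of a genes-by-samples matrix.

    Applied within-sample (across genes, per column) and within-gene (across
    samples, per row), in the given order.  Output values lie in [0, 1].
    """
    out = gene_by_sample.to_numpy(dtype=float).copy()
    for step in order:
        if step == "sample":
            for j in range(out.shape[1]):
                out[:, j] = _srs_vector(out[:, j])
        elif step == "gene":
            for i in range(out.shape[0]):
                out[i, :] = _srs_vector(out[i, :])
        else:
            raise ValueError("order entries must be 'sample' or 'gene'")
    return pd.DataFrame(out, index=gene_by_sample.index, columns=gene_by_sample.columns)


def spatial_parcels(
    coords: np.ndarray, n_regions: int = 30, seed: int = 0
) -> np.ndarray:
    """Spatial k-means parcels over sample coordinates (region labels)."""
    coords = np.asarray(coords, dtype=float)
    _, labels = kmeans2(coords, n_regions, minit="++", seed=seed)
    return labels


def differential_stability(
    gene_by_sample: pd.DataFrame,
    donors: pd.Series | np.ndarray,
    regions: pd.Series | np.ndarray,
    method: str = "spearman",
) -> pd.Series:
    """Inter-donor consistency of each gene's regional expression profile.

    Samples are aggregated to region means per donor; for every donor pair
    the gene's profiles over shared regions are correlated (Spearman by
    default, robust to per-donor monotone distortion) and DS is the mean
    over pairs.  Pairs sharing fewer than two regions are skipped; a gene
    with zero variance within a pair contributes 0 for that pair.
    """
    donors = np.asarray(donors)
    regions = np.asarray(regions)
    uniq_donors = sorted(set(donors.tolist()))
    if len(uniq_donors) < 2:
        raise ValueError("differential stability requires at least two donors")
    X = gene_by_sample.to_numpy(dtype=float)
    # region-mean profile per donor: dict donor -> (regions_present, genes x n_regions)
    profiles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for d in uniq_donors:
        cols = donors == d
        regs = regions[cols]
        uniq_r = np.unique(regs)
        prof = np.column_stack([X[:, cols][:, regs == r].mean(axis=1) for r in uniq_r])
        profiles[d] = (uniq_r, prof)
    n_genes = X.shape[0]
    acc = np.zeros(n_genes)
    n_pairs = 0
    for i, d1 in enumerate(uniq_donors):
        for d2 in uniq_donors[i + 1 :]:
            r1, p1 = profiles[d1]
            r2, p2 = profiles[d2]
            shared, i1, i2 = np.intersect1d(r1, r2, return_indices=True)
            if len(shared) < 2:
                logger.warning("donor pair (%s, %s): <2 shared regions, skipped", d1, d2)
                continue
            a, b = p1[:, i1], p2[:, i2]
            if method == "spearman":
                a = stats.rankdata(a, axis=1)
                b = stats.rankdata(b, axis=1)
            elif method != "pearson":
                raise ValueError("method must be 'spearman' or 'pearson'")
            acc += _rowwise_pearson(a, b)
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no donor pair shares two or more regions")
    return pd.Series(acc / n_pairs, index=gene_by_sample.index, name="ds")


def filter_top_fraction(ds: pd.Series, fraction: float = 0.5) -> pd.Index:
    """Genes in the top ``fraction`` by DS: exactly ceil(fraction * G) kept,
    ties broken by gene id for determinism."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = int(np.ceil(fraction * len(ds)))
    order = ds.sort_index().sort_values(ascending=False, kind="stable")
    return order.index[:n_keep].sort_values()


def restrict_to_mask(samples: pd.DataFrame, grid: VolumeGrid) -> np.ndarray:
    """Boolean keep-flag per sample: nearest voxel inside the analysis mask."""
    coords = samples[["x", "y", "z"]].to_numpy(dtype=float)
    ijk = np.atleast_2d(grid.nearest_voxel(coords))
    ok = np.atleast_1d(grid.in_bounds(ijk))
    keep = np.zeros(len(samples), dtype=bool)
    keep[ok] = grid.mask[ijk[ok, 0], ijk[ok, 1], ijk[ok, 2]]
    if not keep.any():
        raise ValueError("all samples fall outside the analysis mask")
    logger.info("mask restriction: %d -> %d samples", len(samples), int(keep.sum()))
    return keep


def preprocess_atlas(
    bundle: AtlasBundle,
    grid: VolumeGrid,
    min_fraction: float = 0.5,
    min_r: float = 0.2,
    ds_fraction: float = 0.5,
    n_regions: int = 30,
    left_only: bool = True,
    seed: int = 0,
    ds_method: str = "spearman",
) -> SampleGeneMatrix:
    """Full preprocessing chain producing the normalized sample-by-gene matrix.

    With ``left_only`` (default), right-hemisphere samples (x > 0) are
    dropped first — only a minority of donors contribute right-hemisphere
    tissue, so restricting to the left avoids a donor-coverage imbalance.
    """
    samples = bundle.samples.copy()
    if left_only:
        keep = samples["x"].to_numpy() <= 0.0
        logger.info("left-hemisphere restriction: %d -> %d samples", len(samples), int(keep.sum()))
        samples = samples.loc[keep]
    sample_ids = samples["sample_id"].tolist()
    expr = bundle.expression[sample_ids]

    expr = filter_probes_by_intensity(expr, bundle.above_background[sample_ids], min_fraction)
    gene_expr = select_probe_per_gene(
        expr, bundle.annotation, bundle.rnaseq[sample_ids] if bundle.rnaseq is not None else None, min_r
    )
    norm = srs_normalize(gene_expr)

    region = spatial_parcels(samples[["x", "y", "z"]].to_numpy(), n_regions, seed)
    ds = differential_stability(norm, samples["donor"].to_numpy(), region, ds_method)
    kept_genes = filter_top_fraction(ds, ds_fraction)
    norm = norm.loc[kept_genes]

    keep = restrict_to_mask(samples, grid)
    samples = samples.loc[keep].reset_index(drop=True)
    data = norm[samples["sample_id"].tolist()].T
    data.index = samples["sample_id"]
    return SampleGeneMatrix(data=data, meta=samples, ds=ds.loc[kept_genes])
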