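"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis chain assumes:
peak tables from group VBM contrasts with planted effect loci, a donor-based
expression atlas whose signal genes track the effect map at chosen spatial
correlations, flat gene-category annotations enriched for those genes,
confidence-scored interaction graphs with planted hubs, and smooth
receptor/transporter maps with planted spatial correlations.  Every generator
is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .volumes import PeakRecord, StatMap, Study, StudySet, VolumeGrid

__all__ = [
    "GroundTruth",
    "EffectLocus",
    "synthetic_gm_mask",
    "smooth_field",
    "effect_map_from_truth",
    "simulate_study_set",
    "simulate_expression_atlas",
    "simulate_category_sets",
    "simulate_ppi_edges",
    "simulate_receptor_maps",
    "AtlasBundle",
    "write_gmt",
    "read_gmt",
    "demo_truth",
]


@dataclass
class EffectLocus:
    xyz: tuple[float, float, float]
    sign: str  # "increase" | "decrease"
    d: float  # unsigned effect size (Cohen's d scale)

    @property
    def signed_d(self) -> float:
        return self.d if self.sign == "increase" else -self.d


@dataclass
class GroundTruth:
    """Planted quantities a generated dataset must let the pipeline recover."""

    effect_loci: list[EffectLocus] = field(default_factory=list)
    signal_genes: list[tuple[str, float]] = field(default_factory=list)
    enriched_categories: list[str] = field(default_factory=list)
    hub_nodes: list[str] = field(default_factory=list)
    receptor_truth: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for _, rho in self.signal_genes:
            if abs(rho) > 1:
                raise ValueError("signal-gene correlation must satisfy |rho| <= 1")
        for rho in self.receptor_truth.values():
            if abs(rho) > 1:
                raise ValueError("receptor correlation must satisfy |rho| <= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["effect_loci"] = [EffectLocus(tuple(e["xyz"]), e["sign"], e["d"]) for e in d["effect_loci"]]
        d["signal_genes"] = [tuple(g) for g in d["signal_genes"]]
        return cls(**d)


def demo_truth(seed: int = 0, d: float = 0.8) -> GroundTruth:
    """Ground truth used by the demo: two loci mirroring a basal-ganglia
    decrease and an orbitofrontal increase, 60 signal genes, five enriched
    categories, ten hubs, and a nine-system receptor panel."""
    rng = np.random.default_rng(seed)
    signal = [(f"SIG{i:03d}", float(s * 0.7)) for i, s in enumerate(rng.choice([-1, 1], 60))]
    return GroundTruth(
        effect_loci=[
            EffectLocus((-32.0, -6.0, -4.0), "decrease", d),
            EffectLocus((6.0, 20.0, -26.0), "increase", d),
        ],
        signal_genes=signal,
        enriched_categories=[f"CAT_ENR_{i:02d}" for i in range(5)],
        hub_nodes=[f"HUB{i:02d}" for i in range(10)],
        receptor_truth={
            "5HT4": -0.30,
            "D1": -0.35,
            "D2": -0.36,
            "DAT": -0.32,
            "VAChT": -0.38,
            "5HT1a": 0.0,
            "GABAa": 0.0,
            "NAT": 0.0,
            "mGluR5": 0.0,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fields and masks


def synthetic_gm_mask(voxel_size: float = 4.0) -> VolumeGrid:
    """MNI-box grid with an ellipsoidal stand-in for a gray-matter mask.

    Semi-axes chosen to enclose roughly adult-brain volume (~1.6 L); center
    matches the MNI bounding-box center.
    """
    grid = VolumeGrid.mni(voxel_size)
    ijk = np.indices(grid.dims).reshape(3, -1).T
    xyz = np.atleast_2d(grid.voxel_to_world(ijk))
    center = np.array([0.0, -18.0, 18.0])
    semi = np.array([72.0, 88.0, 68.0])
    r2 = (((xyz - center) / semi) ** 2).sum(axis=1)
    mask = (r2 <= 1.0).reshape(grid.dims)
    return VolumeGrid(grid.dims, grid.affine, mask)


def smooth_field(
    grid: VolumeGrid, scale_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized spatially autocorrelated Gaussian field on the lattice.

    White noise smoothed with a squared-exponential kernel of the given
    length scale, then re-standardized over the mask (mean 0, SD 1 in-mask).
    """
    white = rng.standard_normal(grid.dims)
    if scale_mm > 0:
        sigma_vox = scale_mm / grid.voxel_size
        fieldv = gaussian_filter(white, sigma=sigma_vox)
    else:
        fieldv = white
    inmask = fieldv[grid.mask]
    fieldv = (fieldv - inmask.mean()) / inmask.std()
    return fieldv


def effect_map_from_truth(
    truth: GroundTruth, grid: VolumeGrid, fwhm: float = 20.0
) -> StatMap:
    """Smooth signed effect-size map implied by the planted loci.

    Gaussian bumps of the stated FWHM at each locus, signed by direction;
    amplitude equals the planted d.  Serves as the spatial template the
    expression and receptor generators correlate against.
    """
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    xyz = grid.mask_world_coords()
    vals = np.zeros(xyz.shape[0])
    for locus in truth.effect_loci:
        d2 = ((xyz - np.asarray(locus.xyz)) ** 2).sum(axis=1)
        bump = locus.signed_d * np.exp(-d2 / (2 * sigma**2))
        keep = np.abs(bump) > np.abs(vals)
        vals[keep] = bump[keep]
    data = np.zeros(grid.dims)
    data[grid.mask] = vals
    return StatMap(grid, data, kind="d")


def _standardize_inmask(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant field")
    return (values - values.mean()) / sd


# ---------------------------------------------------------------------------
# study sets


def simulate_study_set(
    truth: GroundTruth,
    n_studies: int = 15,
    n_range: tuple[int, int] = (13, 67),
    peak_noise_sd: float = 8.0,
    miss_rate: float = 0.0,
    spurious_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    grid: VolumeGrid | None = None,
) -> StudySet:
    """Peak tables for ``n_studies`` two-group VBM contrasts.

    Each study reports each planted locus with probability ``1 - miss_rate``
    at Gaussian-jittered coordinates; the reported t is drawn from the
    noncentral-t sampling distribution implied by the planted d and the
    study's group sizes (ncp = d*sqrt(n1*n2/(n1+n2)), df = n1+n2-2).
    Spurious peaks (rate per study, Poisson) land uniformly in the mask.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if grid is None and spurious_rate > 0:
        grid = synthetic_gm_mask()
    studies = []
    for i in range(n_studies):
        n1 = int(rng.integers(n_range[0], n_range[1] + 1))
        n2 = int(rng.integers(n_range[0], n_range[1] + 1))
        df = n1 + n2 - 2
        peaks: list[PeakRecord] = []
        for locus in truth.effect_loci:
            if rng.uniform() < miss_rate:
                continue
            xyz = np.asarray(locus.xyz, dtype=float) + rng.normal(0, peak_noise_sd, 3)
            ncp = locus.signed_d * np.sqrt(n1 * n2 / (n1 + n2))
            t = float(stats.nct.ppf(rng.uniform(), df, ncp))
            sign = "increase" if t >= 0 else "decrease"
            peaks.append(PeakRecord(xyz, abs(t), "t", "MNI", sign))
        if spurious_rate > 0:
            n_spur = rng.poisson(spurious_rate)
            coords = grid.mask_world_coords()
            for _ in range(n_spur):
                xyz = coords[rng.integers(coords.shape[0])]
                t = float(rng.uniform(2.0, 4.0))
                sign = "increase" if rng.uniform() < 0.5 else "decrease"
                peaks.append(PeakRecord(xyz, t, "t", "MNI", sign))
        studies.append(
            Study(
                f"study{i:02d}",
                n1,
                n2,
                peaks,
                mean_age=float(np.round(rng.uniform(18, 35), 1)),
                illness_duration=float(np.round(rng.uniform(6, 41), 1)),
            )
        )
    return StudySet(studies)


# ---------------------------------------------------------------------------
# expression atlas


@dataclass
class AtlasBundle:
    """Raw synthetic expression-atlas bundle, mirroring a donor microarray
    release: probe-level expression, probe->gene annotation, above-background
    flags, an RNA-seq reference matrix, and per-sample metadata."""

    samples: pd.DataFrame  # sample_id, donor, x, y, z
    expression: pd.DataFrame  # probes x samples
    annotation: pd.DataFrame  # probe_id -> gene
    above_background: pd.DataFrame  # probes x samples, bool
    rnaseq: pd.DataFrame  # genes x samples

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False, float_format="%.4f")
        self.expression.to_csv(outdir / "probes.tsv", sep="\t", float_format="%.6f")
        self.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        self.above_background.astype(int).to_csv(outdir / "background.tsv", sep="\t")
        self.rnaseq.to_csv(outdir / "rnaseq.tsv", sep="\t", float_format="%.6f")

    @classmethod
    def read(cls, outdir: str | Path) -> "AtlasBundle":
        outdir = Path(outdir)
        return cls(
            samples=pd.read_csv(outdir / "samples.tsv", sep="\t"),
            expression=pd.read_csv(outdir / "probes.tsv", sep="\t", index_col=0),
            annotation=pd.read_csv(outdir / "annotation.tsv", sep="\t"),
            above_background=pd.read_csv(outdir / "background.tsv", sep="\t", index_col=0).astype(bool),
            rnaseq=pd.read_csv(outdir / "rnaseq.tsv", sep="\t", index_col=0),
        )


def simulate_expression_atlas(
    truth: GroundTruth,
    grid: VolumeGrid,
    effect_map: StatMap,
    n_donors: int = 6,
    n_samples_per_donor: int = 100,
    n_genes: int = 1000,
    n_probes_per_gene: int = 2,
    noise_sd: float = 1.0,
    frac_outside_mask: float = 0.3,
    frac_low_intensity: float = 0.15,
    frac_dropout_genes: float = 0.02,
    null_smooth_share: float = 0.5,
    signal_smooth_share: float = 0.8,
    autocorr_scale: float = 10.0,
    n_noise_basis: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AtlasBundle:
    """Donor-based probe-level atlas whose signal genes track the effect map.

    Signal genes (named in ``truth.signal_genes``) get expression
    ``rho * z(effect at sample) + sqrt(1-rho^2) * eps`` where eps is unit
    spatially structured noise orthogonal to the effect template, so the
    realized in-mask spatial correlation with the effect map equals rho.
    Null genes are spatially autocorrelated noise built from a shared
    smooth-field basis; signal genes carry a larger smooth (donor-consistent)
    noise share than null genes, mirroring the higher inter-donor stability
    of genes with anatomically organized expression.  Each gene carries one faithful probe plus degraded
    ones; a chosen probe fraction fails the background-intensity rule, and a
    chosen gene fraction has only degraded probes (later dropped by the
    RNA-seq correlation filter).  Donors beyond the first two contribute only
    left-hemisphere (x <= 0) samples, mirroring the donor design of human
    atlas data.
    """
    if n_donors < 2:
        raise ValueError("differential stability needs at least two donors")
    rng = rng if rng is not None else np.random.default_rng(seed)

    # --- sample coordinates: voxel centers in/out of mask per donor
    mask_flat = grid.mask.reshape(-1)
    ijk_all = np.indices(grid.dims).reshape(3, -1).T
    xyz_all = np.atleast_2d(grid.voxel_to_world(ijk_all))
    left = xyz_all[:, 0] <= 0.0
    rows = []
    for d in range(n_donors):
        bilateral = d < 2
        allowed_in = mask_flat & (left | bilateral)
        allowed_out = (~mask_flat) & (left | bilateral)
        n_out = int(round(frac_outside_mask * n_samples_per_donor))
        n_in = n_samples_per_donor - n_out
        pick_in = rng.choice(np.flatnonzero(allowed_in), size=n_in, replace=False)
        pick_out = rng.choice(np.flatnonzero(allowed_out), size=n_out, replace=False)
        for v in np.concatenate([pick_in, pick_out]):
            rows.append((f"donor{d}", *xyz_all[v]))
    samples = pd.DataFrame(rows, columns=["donor", "x", "y", "z"])
    samples.insert(0, "sample_id", [f"S{i:04d}" for i in range(len(samples))])
    n_samples = len(samples)
    coords = samples[["x", "y", "z"]].to_numpy()

    # --- effect template at samples, standardized over in-mask samples
    vox = grid.nearest_voxel(coords)
    eff = effect_map.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    in_mask = grid.mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    mu, sd = eff[in_mask].mean(), eff[in_mask].std()
    eff_z = (eff - mu) / sd

    # --- gene-level expression
    gene_ids = [g for g, _ in truth.signal_genes]
    gene_ids += [f"G{i:04d}" for i in range(n_genes - len(gene_ids))]
    gene_ids = gene_ids[:n_genes]
    basis = np.column_stack(
        [
            smooth_field(grid, autocorr_scale, rng)[vox[:, 0], vox[:, 1], vox[:, 2]]
            for _ in range(n_noise_basis)
        ]
    )
    expr = np.empty((n_genes, n_samples))
    rho_by_gene = dict(truth.signal_genes)
    eff_in = eff_z[in_mask]

    def structured_noise(share: float) -> np.ndarray:
        combo = basis @ (rng.standard_normal(n_noise_basis) / np.sqrt(n_noise_basis))
        white = rng.standard_normal(n_samples)
        return share * combo + np.sqrt(max(0.0, 1 - share**2)) * white

    for gi, g in enumerate(gene_ids):
        rho = rho_by_gene.get(g, 0.0)
        if rho != 0.0:
            # residual noise is spatially structured (donor-consistent, like
            # real co-expression) and orthogonalized against the effect
            # template over in-mask samples, so the realized in-mask spatial
            # correlation equals rho before normalization
            eps = structured_noise(signal_smooth_share)
            eps = eps - (eps[in_mask] @ eff_in) / (eff_in @ eff_in) * eff_z
            eps = (eps - eps[in_mask].mean()) / eps[in_mask].std()
            expr[gi] = rho * eff_z + np.sqrt(1 - rho**2) * eps
        else:
            expr[gi] = structured_noise(null_smooth_share)
    expr *= noise_sd if noise_sd > 0 else 1.0

    # --- probes: probe 0 faithful, others degraded; dropout genes all degraded
    n_drop = int(round(frac_dropout_genes * n_genes))
    dropout = set(
        rng.choice([g for g in gene_ids if g not in rho_by_gene], size=n_drop, replace=False)
    ) if n_drop else set()
    probe_rows, probe_expr = [], []
    for gi, g in enumerate(gene_ids):
        for p in range(n_probes_per_gene):
            pid = f"P_{g}_{p}"
            probe_rows.append((pid, g))
            faithful = (p == 0) and (g not in dropout)
            if faithful:
                probe_expr.append(expr[gi] + 0.1 * rng.standard_normal(n_samples))
            else:
                probe_expr.append(0.1 * expr[gi] + rng.standard_normal(n_samples))
    annotation = pd.DataFrame(probe_rows, columns=["probe_id", "gene"])
    expression = pd.DataFrame(
        np.asarray(probe_expr), index=annotation["probe_id"], columns=samples["sample_id"]
    )

    # --- background flags: a chosen probe fraction fails the 50% rule
    n_probes = len(annotation)
    fail = rng.uniform(size=n_probes) < frac_low_intensity
    p_above = np.where(fail, 0.25, 0.95)
    above = rng.uniform(size=(n_probes, n_samples)) < p_above[:, None]
    above_background = pd.DataFrame(
        above, index=annotation["probe_id"], columns=samples["sample_id"]
    )

    # --- RNA-seq reference correlated with the faithful probe
    rnaseq = pd.DataFrame(
        expr + 0.6 * rng.standard_normal(expr.shape),
        index=pd.Index(gene_ids, name="gene"),
        columns=samples["sample_id"],
    )
    return AtlasBundle(samples, expression, annotation, above_background, rnaseq)


# ---------------------------------------------------------------------------
# category sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        out[parts[0]] = parts[2:]
    return out


def simulate_category_sets(
    truth: GroundTruth,
    genes: list[str],
    n_categories: int = 200,
    size_range: tuple[int, int] = (10, 20),
    enriched_fraction: float = 0.8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Flat gene-category annotation (GMT-style) with planted enrichment.

    Categories named in ``truth.enriched_categories`` draw
    ``enriched_fraction`` of their members from the signal genes — from a
    single correlation-sign group per category (enrichment is directional:
    mixing positively and negatively correlated members would cancel in the
    category mean); the rest draw uniformly from ``genes``.  Sizes are
    uniform in ``size_range``.
    """
    if size_range[1] > len(genes):
        raise ValueError("size_range exceeds the available gene universe")
    rng = rng if rng is not None else np.random.default_rng(seed)
    universe = set(genes)
    pos = [g for g, r in truth.signal_genes if g in universe and r > 0]
    neg = [g for g, r in truth.signal_genes if g in universe and r < 0]
    groups = [grp for grp in (pos, neg) if grp]
    sets: dict[str, list[str]] = {}
    for ci, name in enumerate(truth.enriched_categories):
        signal = groups[ci % len(groups)] if groups else []
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        n_sig = min(int(np.ceil(enriched_fraction * size)), len(signal))
        members = list(rng.choice(signal, size=n_sig, replace=False))
        others = [g for g in genes if g not in set(members)]
        members += list(rng.choice(others, size=size - n_sig, replace=False))
        sets[name] = sorted(members)
    for i in range(n_categories - len(truth.enriched_categories)):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        sets[f"CAT_NULL_{i:04d}"] = sorted(rng.choice(genes, size=size, replace=False))
    return sets


def simulate_specificity_panel(
    truth: GroundTruth,
    genes: list[str],
    labels: tuple[str, ...] = (
        "brain",
        "pituitary",
        "heart",
        "liver",
        "kidney",
        "lung",
        "muscle",
        "spleen",
    ),
    planted: tuple[str, ...] = ("brain",),
    set_size: int = 80,
    enriched_fraction: float = 0.6,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Specificity gene sets (tissue/cell-type/development style panel).

    Labels in ``planted`` draw ``enriched_fraction`` of their members from
    the signal genes; the remaining labels draw uniformly.  Stands in for
    precomputed specificity-index (pSI) sets.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    signal = [g for g, _ in truth.signal_genes if g in set(genes)]
    panel: dict[str, list[str]] = {}
    for label in labels:
        if label in planted:
            n_sig = min(int(np.ceil(enriched_fraction * set_size)), len(signal))
            members = list(rng.choice(signal, size=n_sig, replace=False))
            others = [g for g in genes if g not in set(members)]
            members += list(rng.choice(others, size=set_size - n_sig, replace=False))
        else:
            members = list(rng.choice(genes, size=set_size, replace=False))
        panel[label] = sorted(members)
    return panel


# ---------------------------------------------------------------------------
# PPI edge lists


def simulate_ppi_edges(
    truth: GroundTruth,
    n_nodes: int = 100,
    background_degree: float = 6.0,
    hub_degree: int = 30,
    low_conf_frac: float = 0.3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Confidence-scored undirected edge list with planted high-degree hubs.

    Background edges follow an Erdos-Renyi layer with the stated expected
    degree; each planted hub is then topped up to ``hub_degree`` partners.
    Hub-incident edges score in [0.9, 1); a ``low_conf_frac`` share of
    background edges scores below the 0.9 confidence cutoff.
    """
    if hub_degree <= background_degree:
        raise ValueError("hub_degree must exceed background_degree")
    rng = rng if rng is not None else np.random.default_rng(seed)
    hubs = list(truth.hub_nodes)
    others = [f"N{i:04d}" for i in range(n_nodes - len(hubs))]
    nodes = hubs + others
    p_bg = background_degree / (n_nodes - 1)
    edges: dict[tuple[str, str], float] = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.uniform() < p_bg:
                if rng.uniform() < low_conf_frac:
                    score = rng.uniform(0.4, 0.9)
                else:
                    score = rng.uniform(0.9, 1.0)
                edges[(nodes[i], nodes[j])] = float(score)
    deg: dict[str, int] = {n: 0 for n in nodes}
    for (a, b), s in edges.items():
        if s >= 0.9:
            deg[a] += 1
            deg[b] += 1
    for h in hubs:
        candidates = [n for n in nodes if n != h]
        rng.shuffle(candidates)
        for c in candidates:
            if deg[h] >= hub_degree:
                break
            key = (h, c) if (h, c) in edges else (c, h) if (c, h) in edges else (h, c)
            if edges.get(key, 0.0) >= 0.9:
                continue
            edges[key] = float(rng.uniform(0.9, 1.0))
            deg[h] += 1
            deg[c] += 1
    df = pd.DataFrame(
        [(a, b, s) for (a, b), s in edges.items()],
        columns=["node1", "node2", "combined_score"],
    )
    return df.sort_values(["node1", "node2"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# receptor maps


def simulate_receptor_maps(
    truth: GroundTruth,
    grid: VolumeGrid,
    effect_map: StatMap,
    autocorr_scale: float = 10.0,
    exact: bool = True,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, StatMap]:
    """Smooth receptor/transporter maps with planted spatial correlations.

    Each map mixes the standardized effect map with a standardized
    autocorrelated Gaussian field:  ``rho * z(effect) + sqrt(1-rho^2) * eps``.
    With ``exact=True`` (default) the noise field is first orthogonalized
    against the effect map over the mask, so the realized in-mask Pearson
    correlation equals rho exactly; with ``exact=False`` the correlation only
    converges to rho as the number of independent spatial degrees of freedom
    grows.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    eff = _standardize_inmask(effect_map.values)
    out: dict[str, StatMap] = {}
    for name, rho in truth.receptor_truth.items():
        eps = smooth_field(grid, autocorr_scale, rng)[grid.mask]
        if exact:
            eps = eps - (eps @ eff) / (eff @ eff) * eff
        eps = _standardize_inmask(eps)
        vals = rho * eff + np.sqrt(1 - rho**2) * eps
        data = np.zeros(grid.dims)
        data[grid.mask] = vals
        out[name] = StatMap(grid, data, kind="z")
    return out
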