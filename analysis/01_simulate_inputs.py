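#!/usr/bin/env python
"""Generate the full synthetic input bundle with known ground truth.

Writes every input the downstream stages consume — peak table, GM mask,
expression-atlas bundle, category and specificity GMT files, PPI edge list,
receptor map panel — plus the ground-truth sidecar, under results/inputs/.
"""

import argparse
import json
from pathlib import Path

from imtx import synth
from imtx import volumes as vol


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    ap.add_argument("--voxel-size", type=float, default=6.0)
    ap.add_argument("--n-genes", type=int, default=400)
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    truth = synth.demo_truth(args.seed)
    truth.to_json(out / "ground_truth.json")
    grid = synth.synthetic_gm_mask(args.voxel_size)
    vol.write_mask(grid, out / "gm_mask.nii")

    studies = synth.simulate_study_set(truth, seed=args.seed, grid=grid)
    vol.write_peak_table(studies, out / "peaks.csv")

    # expression and receptor generators plant correlations against a smooth
    # template with the planted effect topography
    effect = synth.effect_map_from_truth(truth, grid)
    vol.write_stat_map(effect, out / "effect_template.nii")
    atlas = synth.simulate_expression_atlas(
        truth, grid, effect, n_genes=args.n_genes, seed=args.seed + 1
    )
    atlas.write(out / "atlas")

    genes = list(atlas.rnaseq.index)
    synth.write_gmt(
        synth.simulate_category_sets(truth, genes, n_categories=80, seed=args.seed + 2),
        out / "categories.gmt",
    )
    synth.write_gmt(
        synth.simulate_specificity_panel(truth, genes, seed=args.seed + 3),
        out / "specificity_panel.gmt",
    )
    synth.simulate_ppi_edges(truth, seed=args.seed + 4).to_csv(
        out / "ppi_edges.tsv", sep="\t", index=False, float_format="%.4f"
    )
    rmaps = synth.simulate_receptor_maps(truth, grid, effect, seed=args.seed + 5)
    rdir = out / "receptor_maps"
    rdir.mkdir(exist_ok=True)
    for name, m in rmaps.items():
        vol.write_stat_map(m, rdir / f"{name}.nii")
    (rdir / "manifest.json").write_text(json.dumps({"maps": sorted(rmaps)}, indent=2))

    print(f"{len(studies)} studies ({studies.n_peaks} peaks), "
          f"{len(atlas.annotation)} probes / {args.n_genes} genes, "
          f"{len(rmaps)} receptor maps -> {out}")


if __name__ == "__main__":
    main()
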