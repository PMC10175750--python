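#!/usr/bin/env python
"""Generate the synthetic study datasets.

Writes, under results/synthetic_study/: the fluctuating-asymmetry (FA)
datasets for both species (87 and 96 males, left+right wings measured
twice), the common-garden isofemale-line dataset (74 lines, 7 populations,
5 rearing temperatures, both sexes), the 36-species divergence dataset on
a Grafen-scaled cladogram, and the ground-truth covariance matrices the
generator used — so every later stage can be checked against known truth.
"""

import argparse
from pathlib import Path

import devbias
from devbias.covmatrix import CovMatrix
from devbias.io import write_long_csv, write_tps
from devbias.simulate import (default_spec, simulate_fa_dataset,
                              simulate_line_dataset, simulate_species_dataset)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic_study"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    spec = default_spec(seed=args.seed)
    fa_a = simulate_fa_dataset(spec, species="A")
    fa_b = simulate_fa_dataset(spec, species="B")
    write_tps(fa_a, out / "fa_species_A.tps")
    write_tps(fa_b, out / "fa_species_B.tps")
    print(f"FA datasets: {len(fa_a)} wings (species A), {len(fa_b)} (species B)")

    line = simulate_line_dataset(spec)
    write_long_csv(line, out / "line_dataset.csv",
                   meta={"seed": args.seed, "design": "common garden"})
    line.factors.to_csv(out / "line_factors.csv", index=False)
    print(f"common-garden dataset: {len(line)} wings, "
          f"{line.factors['line'].nunique()} lines, "
          f"{line.factors['population'].nunique()} populations")

    sp_data, tree = simulate_species_dataset(spec)
    write_long_csv(sp_data, out / "species_dataset.csv",
                   meta={"seed": args.seed, "design": "interspecific"})
    sp_data.factors.to_csv(out / "species_factors.csv", index=False)
    (out / "cladogram.nwk").write_text(
        tree.as_string(schema="newick").strip() + "\n")
    print(f"divergence dataset: {len(sp_data)} wings, "
          f"{sp_data.factors['species'].nunique()} species")

    for name, mat, label in (
            ("D_true_A", spec.D_true, "D"), ("D_true_B", spec.D2_true, "D"),
            ("P_true_A", spec.P_ind_true, "P"), ("P_true_B", spec.P2_ind_true, "P"),
            ("G_true_A", spec.G_true, "G"), ("R_true", spec.R_true, "R")):
        CovMatrix(mat, label=label, source="generator ground truth",
                  validate=False).to_csv(out / f"{name}.csv")
    print(f"ground-truth matrices written to {out}")


if __name__ == "__main__":
    main()
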