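#!/usr/bin/env python
"""Generate the four synthetic data cohorts and write them to disk.

Produces, under results/sim/:
  titers.csv                     longitudinal antibody titers (two groups,
                                 group-specific waning slopes planted)
  repertoires.tsv + panel refs   pre/post CDR3beta repertoires with an
                                 HD-only post-vaccination spike expansion
  expression .mtx/.tsv sidecars  NB count matrix with an APRIL-module
                                 down-shift planted in SMM post-vaccination
  npx.csv + burden.csv           paired proteomics with an IL-1B response
                                 gradient and an APRIL-burden link
  truth.json                     every planted effect, exactly as configured
"""

import argparse
import json
from pathlib import Path

from precvax.io import write_cell_matrix, write_gene_module, write_npx_csv, write_titer_csv
from precvax.synth import (
    APRIL_MODULE,
    ExprSimConfig,
    NpxSimConfig,
    RepertoireSimConfig,
    TiterSimConfig,
    make_reference_lists,
    simulate_expression_cohort,
    simulate_npx_cohort,
    simulate_repertoire_cohort,
    simulate_titer_cohort,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    truth = {}

    titers, truth["titers"] = simulate_titer_cohort(TiterSimConfig(seed=args.seed))
    write_titer_csv(titers, out / "titers.csv")
    print(f"titers: {titers['individual_id'].nunique()} patients, {len(titers)} samples")

    refs = make_reference_lists(seed=args.seed + 101)
    write_gene_module(refs["spike"], out / "spike_refs.txt")
    write_gene_module(refs["cef"], out / "cef_refs.txt")
    rep_cfg = RepertoireSimConfig(
        planted_spike_post={"HD": 0.10, "MGUS": 0.02, "SMM": 0.02}, seed=args.seed + 1
    )
    repertoires, truth["repertoires"] = simulate_repertoire_cohort(rep_cfg, refs)
    repertoires.rename(columns={"cdr3_aa": "junction_aa"}).assign(locus="TRB").to_csv(
        out / "repertoires.tsv", sep="\t", index=False
    )
    print(f"repertoires: {len(repertoires)} clonotype records "
          f"({repertoires['individual_id'].nunique()} individuals x pre/post)")

    expr_cfg = ExprSimConfig(module_shift=-0.4, seed=args.seed + 2)
    cm, truth["expression"] = simulate_expression_cohort(expr_cfg)
    write_cell_matrix(cm, out / "expr.mtx", out / "expr_genes.tsv", out / "expr_cells.tsv")
    write_gene_module(APRIL_MODULE, out / "april_module.txt")
    print(f"expression: {cm.X.shape[0]} cells x {cm.X.shape[1]} genes")

    npx_cfg = NpxSimConfig(
        paired_shift={("IL1B", "HD"): 1.5, ("IL1B", "MGUS"): 0.8,
                      ("IL18", "HD"): 1.2, ("IL18", "MGUS"): 0.8, ("IL18", "SMM"): 0.4},
        # APRIL sits below the healthy baseline in SMM and falls with burden
        april_link={"intercept": 4.2, "slope": 0.8, "noise_sd": 0.2},
        seed=args.seed + 3,
    )
    npx, burden, truth["npx"] = simulate_npx_cohort(npx_cfg)
    write_npx_csv(npx, out / "npx.csv")
    burden.to_csv(out / "burden.csv", index=False)
    print(f"proteomics: {npx['protein'].nunique()} proteins, "
          f"{npx['individual_id'].nunique()} individuals")

    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str) + "\n")
    print(f"wrote cohorts and truth record to {out}/")


if __name__ == "__main__":
    main()
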