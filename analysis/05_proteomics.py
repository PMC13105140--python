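#!/usr/bin/env python
"""Proteomic response panels on the simulated NPX cohort.

Runs the paired pre/post signed-rank panel (both BH family conventions),
the cross-group rank-sum panels per timepoint, and the APRIL vs
tumor-burden Spearman correlation.  Writes results/proteomics.json and the
panel tables as CSV.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from precvax.io import read_npx_csv
from precvax.proteomics import burden_correlation, cross_group_panel, paired_response_panel


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--npx", type=Path, default=Path("results/sim/npx.csv"))
    ap.add_argument("--burden", type=Path, default=Path("results/sim/burden.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    npx = read_npx_csv(args.npx)
    paired = paired_response_panel(npx, family_mode="per_protein_across_groups")
    paired.to_csv(args.outdir / "paired_panel.csv", index=False)
    hits = paired[paired["q"] < 0.05].sort_values("q")
    print(f"paired responses at q<0.05 (per-protein families): {len(hits)}")
    for _, row in hits.head(8).iterrows():
        print(f"  {row['protein']:10s} {row['group']:5s} q={row['q']:.3g} "
              f"r={row['effect_r']:+.2f} (n={row['n_pairs']})")

    cross = {tp: cross_group_panel(npx, tp) for tp in ("pre", "post")}
    for tp, table in cross.items():
        table.to_csv(args.outdir / f"cross_group_{tp}.csv", index=False)
        print(f"cross-group panel at {tp}: {len(table)} tests, "
              f"{int((table['q'] < 0.05).sum())} at q<0.05")

    result = {"paired_q05": hits.to_dict(orient="records")}
    burden = pd.read_csv(args.burden)
    if not burden.empty:
        corr, _ = burden_correlation(npx, burden.set_index("individual_id")["m_spike"])
        print(f"APRIL vs M-spike (post): rho={corr.rho:+.3f}, p={corr.p:.2e}, n={corr.n}")
        result["burden_correlation"] = corr.to_dict()

    (args.outdir / "proteomics.json").write_text(json.dumps(result, indent=2) + "\n")
    print(f"wrote {args.outdir}/proteomics.json and panel CSVs")


if __name__ == "__main__":
    main()
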