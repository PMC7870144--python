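"""Single-cell differential expression and gene-set enrichment.

Simulates a neurons-versus-progenitors count matrix per species group,
applies the cell and gene QC filters, calls Wilcoxon DEGs at the
adjusted-p < 0.05 / log2FC > 0.25 cutoffs, runs binomial and Fisher/FDR
gene-set enrichment against the detected-gene background, correlates
sub-cluster enrichment profiles, and writes tables under
results/transcriptomics/.

Run from the repository root: python analysis/04_transcriptomics.py
"""
from pathlib import Path

import numpy as np

from ineuron.pipeline import StudyConfig, run_transcriptomics_stage

SEED = 1
OUT = Path("results/transcriptomics")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = StudyConfig(seed=SEED)
    rng = np.random.default_rng(SEED)
    tables = run_transcriptomics_stage(cfg, rng)
    for name, df in tables.items():
        df.to_csv(OUT / f"{name}.csv", index=False, float_format="%.10g")

    degs = tables["deg_table"]
    for group, sub in degs.groupby("group"):
        n = int(sub.deg_flag.sum())
        print(f"{group}: {n} genes higher in neurons "
              f"(of {len(sub)} tested)")

    enr = tables["enrichment_table"]
    for (group, test), sub in enr.groupby(["group", "test"]):
        n = int(sub.enriched_flag.sum())
        print(f"{group} {test}: {n}/{len(sub)} terms enriched")

    corr = tables["enrichment_correlation"].set_index("profile")
    mask = tables["enrichment_correlation_mask"].set_index("profile")
    print("\nPearson correlation of sub-cluster enrichment profiles "
          "(circled if r > 0.7):")
    for a in corr.index:
        for b in corr.columns:
            if a < b:
                mark = "o" if bool(mask.loc[a, b]) else " "
                print(f"  {a} vs {b}: r = {corr.loc[a, b]:.3f} {mark}")


if __name__ == "__main__":
    main()
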