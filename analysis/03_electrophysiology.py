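"""Electrophysiological maturation of synthetic ape and human neurons.

Simulates whole-cell recordings per age bin (voltage steps, ramp, current
steps, 60-s EPSC traces), extracts passive properties with the package's
estimators, counts action potentials and detects spontaneous EPSCs, and
writes the per-bin summary and two-way ANOVA tables under results/ephys/.

Run from the repository root: python analysis/03_electrophysiology.py
"""
from pathlib import Path

import numpy as np

from ineuron.pipeline import StudyConfig, run_ephys_stage

SEED = 1
OUT = Path("results/ephys")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = StudyConfig(seed=SEED, ephys_cells_per_group_bin=8)
    rng = np.random.default_rng(SEED)
    tables = run_ephys_stage(cfg, rng)
    for name, df in tables.items():
        df.to_csv(OUT / f"{name}.csv", index=False, float_format="%.10g")

    passive = tables["ephys_passive"]
    print("membrane time constant tau = Rcell*Ccell (ms), by species:")
    for group, sub in passive.groupby("group"):
        print(f"  {group:6s} mean {sub.tau_ms.mean():5.1f} ms "
              f"(n={len(sub)})")

    anova = tables["ephys_anova"]
    cc = anova[anova.metric == "ccell_pf"].set_index("factor")
    print("\ntwo-way ANOVA on Ccell (day bin x species):")
    for factor in ("day_bin", "group", "interaction"):
        row = cc.loc[factor]
        print(f"  {factor:12s} F({row.df_num:.0f},{row.df_den:.0f}) = "
              f"{row.F:6.2f}  p = {row.p:.3g}")

    aps = tables["ephys_aps"]
    print("\nmax inducible AP count by age bin:")
    for (bin_label), sub in aps.groupby("day_bin", sort=False):
        means = sub.groupby("group").max_ap_count.mean()
        print(f"  {bin_label:8s} ape {means.get('ape', float('nan')):5.1f}  "
              f"human {means.get('human', float('nan')):5.1f}")

    epsc = tables["ephys_epsc"]
    active = epsc[~epsc.zero_events]
    print(f"\nEPSC: {len(active)}/{len(epsc)} cells with events; "
          f"mean log10 frequency {active.log10_frequency.mean():.2f}")


if __name__ == "__main__":
    main()
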