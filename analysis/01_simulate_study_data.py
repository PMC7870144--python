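"""Generate a ground-truthed synthetic study on disk.

Writes, under results/data/: example traced reconstructions (SWC and HOC),
a four-step + ramp voltage-clamp recording with its metadata sidecar, a
current-clamp step family, a 60-s spontaneous-EPSC trace, and a
negative-binomial count matrix with planted differential expression — the
same file formats the analysis stages read, each with a truth.json.

Run from the repository root: python analysis/01_simulate_study_data.py
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ineuron import morphology as M
from ineuron import synthetic as S
from ineuron.ephys import RampProtocol, StepProtocol, write_trace

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    morph_dir = OUT / "morphology"
    morph_dir.mkdir(exist_ok=True)
    for day in (7, 14, 21, 35):
        m, truth = S.generate_morphology(S.MorphGenParams(), day, rng,
                                         cell_id=f"cell_d{day}")
        M.write_swc(m, morph_dir / f"cell_d{day}.swc")
        M.write_hoc(m, morph_dir / f"cell_d{day}.hoc")
        (morph_dir / f"cell_d{day}.truth.json").write_text(
            json.dumps(truth, indent=1))
        print(f"day {day}: {truth['n_neurites']} neurites, "
              f"{truth['total_length']:.0f} µm total")

    ephys_dir = OUT / "ephys"
    ephys_dir.mkdir(exist_ok=True)
    cell = S.MembraneSimParams(rcell_mohm=600, ccell_pf=28, rs_mohm=16,
                               vrmp_mv=-74.0)
    steps, truth = S.simulate_voltage_clamp(cell, StepProtocol(), rng)
    for i, tr in enumerate(steps):
        write_trace(tr, ephys_dir / f"vc_step{i}.csv",
                    {"mode": "vc", "cell_id": "demo", "Rs_mohm": 16.0})
    ramp, _ = S.simulate_ramp(cell, RampProtocol(), rng)
    write_trace(ramp, ephys_dir / "vc_ramp.csv",
                {"mode": "vc", "cell_id": "demo", "Rs_mohm": 16.0})
    (ephys_dir / "vc.truth.json").write_text(json.dumps(truth, indent=1))
    currents = [-20.0, -10.0] + [10.0 * (i + 1) for i in range(18)]
    spikes = [0, 0] + sorted(rng.integers(0, 25, size=18).tolist())
    cc_traces, cc_truth = S.simulate_current_clamp(cell, currents, spikes,
                                                   rng)
    for i, tr in enumerate(cc_traces):
        write_trace(tr, ephys_dir / f"cc_step{i:02d}.csv", {"mode": "cc"})
    (ephys_dir / "cc.truth.json").write_text(json.dumps(cc_truth, indent=1))
    epsc, epsc_truth = S.simulate_epsc_trace(S.EpscTrainParams(), rng)
    write_trace(epsc, ephys_dir / "epsc_60s.csv",
                {"mode": "vc", "cell_id": "demo"})
    (ephys_dir / "epsc.truth.json").write_text(
        json.dumps(epsc_truth, indent=1))
    print(f"ephys: 4 steps + ramp + 20 current steps + 60 s EPSC trace "
          f"({epsc_truth['n_events']} planted events)")

    sc_dir = OUT / "scrnaseq"
    sc_dir.mkdir(exist_ok=True)
    adata, counts_truth = S.simulate_counts(
        S.CountsGenParams(n_high_mito=5, n_low_depth=5), rng)
    pd.DataFrame(np.asarray(adata.X).T, index=adata.var_names,
                 columns=adata.obs_names).to_csv(sc_dir / "counts.csv")
    adata.obs.to_csv(sc_dir / "cells.csv")
    adata.var.to_csv(sc_dir / "genes.csv")
    (sc_dir / "truth.json").write_text(json.dumps(counts_truth, indent=1))
    print(f"scRNAseq: {adata.n_obs} cells x {adata.n_vars} genes, "
          f"{len(counts_truth['planted_genes'])} planted DEGs")


if __name__ == "__main__":
    main()
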