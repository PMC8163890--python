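#!/usr/bin/env python
"""Comparative-Ct quantification: forward simulation and recovery.

Simulates strain-specific qPCR Ct values from known community compositions
(with and without cycle noise), recovers the compositions by the 2^-Ct
method, and prints the ddCt worked examples.  Writes
results/qpcr_recovery.tsv.
"""

import os

import numpy as np

from lbpdesign.quant import CompositionTable, composition_from_ct, fold_change_ddct
from lbpdesign.synthetic import simulate_ct

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    os.makedirs(OUT, exist_ok=True)
    rng = np.random.default_rng(11)
    strains = [f"strain_{i}" for i in range(8)]
    rows = []
    for sample in range(10):
        w = rng.dirichlet(np.ones(len(strains)))
        truth = CompositionTable(f"s{sample}", dict(zip(strains, map(float, w))))
        for noise in (0.0, 0.25):
            ct = simulate_ct(truth, scale=20.0, noise_sd=noise, seed=sample)
            est = composition_from_ct(ct)
            err = max(abs(est.fractions[t] - truth.fractions[t]) for t in strains)
            rows.append((sample, noise, err))
    with open(os.path.join(OUT, "qpcr_recovery.tsv"), "w") as fh:
        fh.write("sample\tnoise_sd_cycles\tmax_abs_error\n")
        for r in rows:
            fh.write(f"{r[0]}\t{r[1]}\t{r[2]:.3e}\n")
    noise_free = max(r[2] for r in rows if r[1] == 0.0)
    noisy = float(np.median([r[2] for r in rows if r[1] > 0.0]))
    print(f"composition recovery: noise-free max error {noise_free:.2e}; "
          f"0.25-cycle noise median max error {noisy:.3f}")
    print("ddCt worked examples: "
          f"ddCt=0 -> {fold_change_ddct(20, 15, 22, 17):.2f}; "
          f"target 1 cycle earlier -> {fold_change_ddct(19, 15, 20, 15):.2f}; "
          f"ddCt=+2 -> {fold_change_ddct(22, 15, 20, 15):.2f}")


if __name__ == "__main__":
    main()
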