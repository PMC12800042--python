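#!/usr/bin/env python
"""Well-posedness of the fractional therapy model.

Computes the per-equation Lipschitz constants and uniqueness flags for the
triple-therapy setting, then demonstrates Picard contraction on a unit
horizon for a variant where every flag holds.  Writes
results/wellposedness.json and results/picard_psi_norms.csv.

Finding: with full immunotherapy (u2=0.4) the CD4 equation's literal
contraction condition fails (L4 = 1.2501 > Gamma(0.9)); dropping u2 restores
all five flags, and the Picard iterates then contract geometrically onto the
PECE solution (final disagreement < 1e-2 after 8 iterates).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from crcdyn import (FractionalConfig, SolverGrid, default_parameters,
                    make_field, solve_pece, lipschitz_constants,
                    picard_iterate)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = default_parameters(g2=0.2, u1=0.2, u2=0.4, u3=0.5)
report = lipschitz_constants(params, alpha=0.9)
print("triple therapy:   L =", np.round(report.constants, 4),
      "flags =", report.uniqueness_flags)

params0 = params.replace(u2=0.0)
report0 = lipschitz_constants(params0, alpha=0.9)
print("without immuno:   L =", np.round(report0.constants, 4),
      "flags =", report0.uniqueness_flags)

cfg = FractionalConfig(alpha=0.9)
grid = SolverGrid(1.0, 1000)
x0 = np.array([10.0, 0, 0, 0, 0])
seq = picard_iterate(params0, x0, cfg, grid, n_iter=8)
sol = solve_pece(make_field(params0, cfg), x0, cfg, grid)
gap = float(np.max(np.abs(seq.final() - sol.states)))
psi = np.max(seq.successive_diffs, axis=1)
print(f"Picard vs PECE on [0,1]: max gap {gap:.2e}")
print("Psi sup-norms:", np.array2string(psi, precision=3))

(OUT / "wellposedness.json").write_text(json.dumps({
    "triple_therapy": json.loads(report.to_json()),
    "no_immunotherapy": json.loads(report0.to_json()),
    "picard_vs_pece_gap": gap,
}, indent=2) + "\n")
pd.DataFrame({"iterate": np.arange(1, len(psi) + 1),
              "psi_sup_norm": psi}).to_csv(
    OUT / "picard_psi_norms.csv", index=False)
print("wrote", OUT / "wellposedness.json")
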