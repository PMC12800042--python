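#!/usr/bin/env python
"""Equilibria and their stability for the two therapy regimes.

Triple therapy (g2=0.2, u=(0.2, 0.4, 0.5)): only the tumor-free equilibrium
exists and it is asymptotically stable — therapy clears the tumor.
Weak chemotherapy (g2=0.6, u=(0.3, 0.2, 0.01)): a single coexistence
equilibrium appears near (but below) the carrying capacity and is stable —
the tumor persists at a controlled level.

Writes results/equilibria_stability.json.
"""

import json
from pathlib import Path

import numpy as np

from crcdyn import (default_parameters, tumor_free_equilibrium,
                    find_coexistence, assess_equilibrium)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

payload = {}
for label, over in [("triple_therapy", dict(g2=0.2, u1=0.2, u2=0.4, u3=0.5)),
                    ("weak_chemo", dict(g2=0.6, u1=0.3, u2=0.2, u3=0.01))]:
    p = default_parameters(**over)
    entry = {}
    for rep in [tumor_free_equilibrium(p), *find_coexistence(p)]:
        if not rep.exists:
            entry[rep.kind] = {"exists": False, "notes": rep.notes}
            continue
        st = assess_equilibrium(p, rep, alpha=0.9)
        state = rep.as_array()
        print(f"{label} / {rep.kind}: state={np.round(state, 4)} "
              f"classification={st.classification} "
              f"eigs={np.round(np.sort(st.eigenvalues.real), 4)}")
        entry[rep.kind] = {
            "equilibrium": json.loads(rep.to_json()),
            "stability": json.loads(st.to_json()),
        }
    payload[label] = entry

(OUT / "equilibria_stability.json").write_text(
    json.dumps(payload, indent=2) + "\n")
print("wrote", OUT / "equilibria_stability.json")
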