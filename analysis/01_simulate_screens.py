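#!/usr/bin/env python
"""Simulate a paired control/query screen with known planted interactions.

Writes raw colony time-course tables (the format produced downstream of
image quantification) plus the generative truth table under results/sim/.
80 library genes x 4 replicate cultures, imaged every 4 h for 5 days; the
query background halves growth rate (m_true = 0.5) and 10% of genes carry
an additional x0.5 interaction effect.
"""

from pathlib import Path

from qfa.synthetic_data import SimulationConfig, generate_screen_pair, write_simulated_raw

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

cfg = SimulationConfig(
    n_genes=80, n_replicates=4, planted_fraction=0.1,
    planted_effect_range=(0.5, 0.5), noise_sigma=0.05, m_true=0.5, seed=2015,
)

control, query, truth = generate_screen_pair(cfg)
paths = write_simulated_raw(control, query, truth, OUT)

n_planted = int(truth.interacting.sum())
print(f"simulated {len(control)} control and {len(query)} query growth curves")
print(f"{cfg.n_genes} genes, {n_planted} with a planted x0.5 interaction")
for k, p in paths.items():
    print(f"  {k}: {p}")
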