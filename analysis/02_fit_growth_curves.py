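#!/usr/bin/env python
"""Fit generalized logistic curves to every culture and tabulate fitness.

Reads the raw time courses written by 01_simulate_screens.py, chooses a
shared inoculum density x0 (5th percentile of first-timepoint densities of
the control screen), fits (r, K, nu) per culture by bounded multi-start
least squares, and writes per-culture fitness tables
(MDR, MDP, fitness = MDR x MDP) under results/.
"""

from pathlib import Path

from qfa.growth_model import choose_x0
from qfa.io import read_timecourses, write_fitness_table
from qfa.pipeline import fit_screen

ROOT = Path(__file__).resolve().parent.parent / "results"

control = read_timecourses(ROOT / "sim" / "control_timecourse.txt")
query = read_timecourses(ROOT / "sim" / "query_timecourse.txt")

x0 = choose_x0([c.observations[0][1] for c in control])
print(f"shared inoculum density x0 = {x0:.5f} (5th pct of first timepoints)")

for name, curves in (("control", control), ("query", query)):
    entries = fit_screen(curves, x0=x0)
    n_bad = sum(not fit.converged for _, fit, _ in entries)
    out = ROOT / f"{name}_fitness.txt"
    write_fitness_table(entries, out)
    mean_f = sum(rec.fitness for _, _, rec in entries) / len(entries)
    print(f"{name}: {len(entries)} curves fitted ({n_bad} failed), "
          f"mean fitness {mean_f:.2f} -> {out.name}")
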