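#!/usr/bin/env python
"""Call genetic interactions of the query screen against the control screen.

Fits the through-origin multiplicative-model slope m over per-gene mean
fitnesses, Welch-tests each gene's observed query replicates against
m x control replicates, applies Benjamini-Hochberg FDR (q < 0.05), writes
the GIS report and the control-vs-query fitness plot, and scores the calls
against the planted truth from 01_simulate_screens.py.
"""

from pathlib import Path

import pandas as pd

from qfa.io import read_fitness_table, write_gis_report
from qfa.pipeline import run_gis
from qfa.plots import render_fitness_plot

ROOT = Path(__file__).resolve().parent.parent / "results"

ctrl = read_fitness_table(ROOT / "control_fitness.txt")
qry = read_fitness_table(ROOT / "query_fitness.txt")
records, m = run_gis(ctrl, qry, q_threshold=0.05)

out = ROOT / "query.gis.txt"
write_gis_report(records, out)
counts = render_fitness_plot(records, m, ROOT / "fitness_plot.png",
                             title="query vs control")

truth = pd.read_csv(ROOT / "sim" / "truth.txt", sep="\t")
planted = set(truth.loc[truth.interacting, "gene"])
neg = {r.gene for r in records if r.call == "negative"}

print(f"multiplicative-model slope m = {m:.3f}")
print(f"calls at q<0.05: {counts['negative']} negative, "
      f"{counts['positive']} positive of {len(records)} genes")
print(f"planted recovery: {len(neg & planted)}/{len(planted)} found, "
      f"{len(neg - planted)} spurious negative calls")
print(f"report -> {out.name}; plot -> fitness_plot.png")
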