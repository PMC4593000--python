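#!/usr/bin/env python
"""Classify interactors across three query screens and rank by profile.

Simulates three query screens against a common control at screen scale
(2000 genes, 8 replicates, fitness level): 40 genes interact in all three
screens and 40 more in each screen alone. Negative calls are classified
into Venn areas; per-gene fitness profiles over the four screens feed the
similarity search, asking whether the shared interactors cluster together.
Writes the Venn report, the wide profile table and a profile plot under
results/.
"""

from pathlib import Path

import pandas as pd

from qfa.interaction import summarize_screen
from qfa.io import write_profile_table, write_venn_report
from qfa.pipeline import run_gis
from qfa.plots import render_profile_plot
from qfa.profiles import build_profiles, nearest_profiles, venn_classify
from qfa.synthetic_data import simulate_fitness_screens

ROOT = Path(__file__).resolve().parent.parent / "results"
N_GENES, SHARED, UNIQUE = 2000, 40, 40

neg_sets: dict[str, set] = {}
screens = []
control_summ = None
for i in range(3):
    ctrl, qry, truth = simulate_fitness_screens(
        n_genes=N_GENES, n_replicates=8, m_true=0.5,
        planted_fraction=0.0, noise_sigma=0.05, seed=300 + i,
    )
    genes = truth.gene.tolist()
    target = genes[:SHARED] + genes[SHARED + i * UNIQUE:SHARED + (i + 1) * UNIQUE]
    qry = qry.assign(
        fitness=qry.fitness * qry.gene.isin(target).map({True: 0.5, False: 1.0})
    )
    records, m = run_gis(ctrl, qry)
    name = f"query_{i + 1}"
    neg_sets[name] = {r.gene for r in records if r.call == "negative"}
    screens.append((name, summarize_screen(qry, background=name)))
    if control_summ is None:
        control_summ = summarize_screen(ctrl, background="control")
    print(f"{name}: slope {m:.3f}, {len(neg_sets[name])} negative calls")

assignments = venn_classify(neg_sets)
write_venn_report(assignments, ROOT / "venn.txt")
area_counts = pd.Series([a.area for a in assignments]).value_counts()
print("\nVenn areas of negative interactors:")
for area, n in area_counts.items():
    print(f"  {area}: {n}")

pset = build_profiles([("control", control_summ)] + screens)
write_profile_table(pset, ROOT / "profiles.txt")

shared_genes = set(pset.genes[:SHARED])
query_gene = sorted(shared_genes)[0]
top = nearest_profiles(query_gene, pset, k=10, excluded_screens=["control"])
n_shared = sum(g in shared_genes for g, _ in top)
print(f"\nnearest profiles to {query_gene} (control screen ignored):")
for g, d in top[:5]:
    tag = " [shared interactor]" if g in shared_genes else ""
    print(f"  {g}  d={d:.3f}{tag}")
print(f"{n_shared}/10 of its nearest neighbours are fellow shared interactors")

render_profile_plot(pset, [query_gene] + [g for g, _ in top[:3]],
                    ROOT / "profile_plot.png")
print("wrote venn.txt, profiles.txt, profile_plot.png")
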