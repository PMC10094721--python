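"""Exponential (Boltzmann) averaging of the packaged QM/MM barrier tables.

Loads the three per-snapshot hydrogen-abstraction ensembles, prints their
summary statistics, and shows the regioselectivity gap between the H12proS
and H9proR abstraction channels.
"""

from loxtraj import energetics as en

for name in (
    "halox12_h12pros_abstraction",
    "halox12_h9pror_abstraction",
    "pigalox15_h12pros_abstraction",
):
    table = en.load_packaged_table(name)
    s = en.barrier_table_summary(table, temperature=300.0)
    print(f"\n{name} ({s['n']} snapshots)")
    print(f"  barrier min / mean      : {s['barrier_min']:.1f} / {s['barrier_mean']:.2f} kcal/mol")
    print(f"  exponential average     : {s['barrier_exponential_average']:.2f} kcal/mol")
    print(f"  stereo tally            : {s['stereo_tally']}")
    if "printed_exponential_average" in s:
        flag = "DISCREPANCY" if s["discrepancy_vs_printed"] else "consistent"
        print(f"  printed value           : {s['printed_exponential_average']} ({flag})")

h12 = en.load_packaged_table("halox12_h12pros_abstraction")["dE_barrier"]
h9 = en.load_packaged_table("halox12_h9pror_abstraction")["dE_barrier"]
gap = en.compare_ensembles(h12, h9, 300.0)
print(f"\nH9proR - H12proS exponential-average gap: {gap:.2f} kcal/mol")
print("(the lower H12 channel explains why the 14-hydroperoxide dominates)")
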