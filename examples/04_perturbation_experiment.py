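"""A full 4-cavity experiment: control plus three chemical perturbations.

Runs the end-to-end pipeline on a self-contained synthetic configuration:
each cavity is recorded before and after its perturbation, the control
cavity corrects global drifts, and every cavity gets activity ratios,
rate-difference skewness, functional-graph weight differences, community
counts and topology ratios.  Writes the full report bundle to ./out and
prints the headline numbers.
"""

import cavnet as cn

config = {
    "seed": 11,
    "duration": 900.0,           # 15-min recordings keep this demo quick
    "generator": {"n_clusters": 24, "n_communities": 3},
    "analysis": {"n_surrogates": 100},
    "cavities": [
        {"name": "control", "role": "control"},
        {"name": "M", "role": "M",
         "perturbation": {"silenced_fraction": 0.05, "weaken_factor": 0.9}},
        {"name": "Abeta", "role": "Abeta",
         "perturbation": {"silenced_fraction": 0.05, "weaken_factor": 0.8}},
        {"name": "M-Abeta", "role": "M-Abeta",
         "perturbation": {"silenced_fraction": 0.3, "weaken_factor": 0.3}},
    ],
}

summary = cn.run_pipeline(config, "out")

print(f"{'cavity':10s} {'Phi ratio':>9s} {'Psi ratio':>9s} {'gamma':>7s} "
      f"{'moduli':>8s} {'geff':>6s} {'leff':>6s}")
for name, cav in summary["cavities"].items():
    com = cav["communities"]
    moduli = f"{com['n_moduli_before']}->{com['n_moduli_after']}" if com else "-"
    topo = cav["topology_ratios"]
    print(f"{name:10s} {cav['Phi_ratio']:9.2f} {cav['Psi_ratio']:9.2f} "
          f"{cav['gamma']:7.2f} {moduli:>8s} "
          f"{topo['global_efficiency'] or float('nan'):6.2f} "
          f"{topo['local_efficiency'] or float('nan'):6.2f}")
print("\nratios are after/before, drift-corrected by the control cavity;")
print("a ratio < 1 means the quantity fell under the perturbation, and a")
print("negative gamma means the rate-difference distribution is left-skewed")
print("(clusters losing activity dominate). Full report: out/summary.json")
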