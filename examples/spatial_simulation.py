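"""Spatially structured allele frequencies across a 4-level hierarchy.

32 populations on a line, nested in 4 subregions and 2 regions, with
allele frequencies at 10 bi-allelic loci drawn from a truncated Gaussian
whose correlation decays as exp(-delta * distance).  Small delta means
strong, far-reaching spatial structure.  A short sweep (25 replicates per
delta here; the default study runs 100) shows how the diversity
components respond to the strength of spatial structure.
"""

from hierdiv import SimulationConfig, run_experiment

cfg = SimulationConfig(n_reps=25, n_loci=10, seed=42)
results = run_experiment(cfg, deltas=(0.1, 1.0, 6.0))

cols = [
    "d_gamma",
    "d_alpha_population",
    "differentiation_population",
    "differentiation_region",
]
print(results.groupby("delta")[cols].mean().round(3).to_string())
print()
print("Ecosystem gamma rises as structure weakens (more of the frequency")
print("space is explored independently), population-level alpha stays flat")
print("(each population is internally panmictic at any delta), regional")
print("differentiation fades while population-level differentiation grows.")
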