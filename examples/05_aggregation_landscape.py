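"""A50% aggregation landscape and the ΔA50% translational offset.

Simulates a panel whose treatment shifts the aggregation midpoint up by
0.3 decades at fixed chaperone level, bins cells by expression, fits
Boltzmann sigmoids and runs the shared-slope regression of log10(A50%)
against stability.
"""


from holdase.pipeline import PipelineConfig, run_aggregation, run_simulate
from holdase.simulate import SimulationTruth

truth = SimulationTruth(seed=7, agg_x50_offset=0.3, C_treatment=0.0)
cfg = PipelineConfig(seed=7)

tables = run_simulate(cfg, truth=truth, replicates=3)
landscape, reg = run_aggregation(cfg, tables)

print("mutant     log10 A50 control   log10 A50 treatment")
for m in landscape.mutants(["control", "treatment"]):
    print(f"{m:<9}  {landscape.mean_x50(m, 'control'):15.3f}   "
          f"{landscape.mean_x50(m, 'treatment'):16.3f}")
print(f"\nexcluded (too little aggregation): {landscape.excluded}")
print(f"common slope: {reg.slope:.4f} log10 AFU per kJ/mol")
print(f"ΔA50% offset: {reg.deltaA50_offset:+.3f} log10 AFU "
      f"= {10 ** reg.deltaA50_offset:.2f}-fold (truth {truth.agg_x50_offset})")
print(f"extra-sum-of-squares F-test (shared vs separate slopes) p = {reg.f_test_p:.3f}")
print(f"Wilcoxon signed-rank on per-mutant offsets p = {reg.wilcoxon_p:.2e}")
print("\nStable mutants need more biosensor before half the cells aggregate;")
print("the treatment shifts that threshold uniformly across the panel.")
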