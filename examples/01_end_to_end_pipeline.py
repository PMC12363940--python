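"""Run the whole PAS-seq pipeline on a simulated depletion experiment.

Simulates a toy genome with IPA/PROMPT poly(A) sites and internal-priming
decoys, emits reads, trims/aligns/filters/quantifies them, and calls
differential poly(A)-site usage between control (DMSO) and depleted (dTAG)
cells in each compartment.
"""

from paspipe import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    sim=SimulationConfig(
        seed=1,
        n_genes=30,
        base_mean=20.0,
        internal_priming_rate=0.1,
        effect_ipa_log2fc=2.0,     # IPA transcripts accumulate 4-fold
        effect_leak_log2fc=1.0,    # and double again in the cytoplasm
        effect_prompt_log2fc=3.0,  # PROMPTs are stabilised 8-fold
    )
)
report = run_pipeline(config, "example_run")

print(f"reads emitted:            {report.reads_in}")
print(f"failed trimming:          {report.rejected}")
print(f"aligned end-to-end:       {report.aligned}")
print(f"internal-priming removed: {report.filtered_artifact}")
print(f"assigned to known PAS:    {report.assigned}")
print("differential calls by class (per compartment):")
for comp, calls in report.calls_by_class.items():
    up = {k: v for k, v in calls.items() if k.endswith(":up")}
    print(f"  {comp}: {up}")

# The artifact count tracks the simulated 10% internal-priming rate, and
# the up-calls concentrate in the IPA/PROMPT classes: loss of the
# retention factor stabilises exactly the misprocessed RNA classes.
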