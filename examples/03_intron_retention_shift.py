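"""Nucleus-vs-cytoplasm intron retention after depletion.

Simulates junction counts in which 20% of introns - biased 80% toward
last introns - gain cytoplasmic inclusion in depleted cells, then tests
each intron with Fisher's exact test and the significant set for
last-intron positional enrichment.
"""

from paspipe import (
    SimulationConfig,
    compartment_shift,
    generate_annotation,
    intron_position_enrichment,
    simulate_junction_counts,
)

cfg = SimulationConfig(seed=3, n_genes=150, junction_depth=100,
                       frac_introns_spiked=0.2, last_intron_bias=0.8)
ann = generate_annotation(cfg)
table, truth = simulate_junction_counts(ann, cfg)

shift = compartment_shift(table, condition="dTAG", dpsi_min=0.1, fdr=0.05)
sig = shift[shift.significant]
print(f"introns tested: {len(shift)}; significant cytoplasmic shifts: {len(sig)}")
print(f"median delta PSI (cyto - nuc): {shift.delta_psi.median():.3f}")

obs, exp, p = intron_position_enrichment(sig.ordinal.tolist(),
                                         shift.ordinal.tolist())
print(f"last-intron fraction among hits: {obs:.2f} (background {exp:.2f}), p = {p:.2e}")

# A positive median delta PSI and a last-intron fraction far above
# background reproduce the leakage signature: intron-retained transcripts,
# mostly carrying their last intron, escape to the cytoplasm when nuclear
# retention is lost.
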