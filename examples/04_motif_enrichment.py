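"""Motif enrichment in summit-refined peaks against flanking controls.

Peaks are refined to +/-250 bp around the summit; equal-length regions
immediately up- and downstream serve as controls. Occurrences come from an
exact-p-value PWM scanner; enrichment is a hit-density ratio with a
chi-squared test and BH FDR across motifs.
"""

from cistrome_compare import motif_enrichment, synthetic

sim = synthetic.simulate(synthetic.SimulationConfig(seed=7))
pwms = list(sim.truth.pwms) + [
    synthetic.shuffled_decoy(p, seed=7) for p in sim.truth.pwms
]

for line in sim.config.cell_lines[:2]:
    print(f"\n{line}:")
    results = motif_enrichment.enrich_all(
        sim.truth.true_peaks[line], sim.genome, pwms, p_threshold=1e-4
    )
    for r in results:
        print(f"  {r.motif_id:16s} hits {r.hits_peak:3d} vs {r.hits_control:3d} "
              f"log2(ES) {r.log2_es:+.2f}  q {r.q:.2g}")
# Only the special line's peaks are enriched (q < 0.01, log2 ES > 1) for the
# planted motif; the column-shuffled decoy stays near log2(ES) = 0.
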