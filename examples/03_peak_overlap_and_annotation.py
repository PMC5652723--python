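"""Quantify peak sharing between experiments and where peaks fall.

Peaks are shared when they overlap by at least 1 bp; the overlap
coefficient divides shared counts by the smaller peak-set size. Each peak is
also assigned promoter / gene body / intergenic by its summit position.
"""

from cistrome_compare import peak_analysis, synthetic

sim = synthetic.simulate(synthetic.SimulationConfig(seed=7))
peak_sets = {line: peaks for line, peaks in sim.truth.true_peaks.items()}

ov = peak_analysis.overlap_matrix(peak_sets)
print("overlap coefficients (min-normalized):")
print(ov.coefficients.round(2))

print("\ngenomic distribution of summits:")
for line, peaks in peak_sets.items():
    d = peak_analysis.annotate_distribution(peaks, sim.genes)
    print(f"  {line}: promoter {d.fraction('promoter'):.0%}, "
          f"gene body {d.fraction('gene_body'):.0%}, "
          f"intergenic {d.fraction('intergenic'):.0%}")
# The special line shows near-zero overlap with the others and binds mostly
# outside promoters, mirroring a co-factor-recruited cistrome.
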