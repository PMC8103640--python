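"""Genome-size estimation from shotgun reads via the 17-mer histogram.

Simulates error-free 40x reads of a 100 kb genome, builds the canonical
k-mer multiplicity histogram and applies the total-over-peak formula.
"""

from medsweep.kmer import count_kmers, estimate_genome_size
from medsweep.simulate import sim_diploid_reads

GENOME_LEN = 100_000
_, reads = sim_diploid_reads(GENOME_LEN, coverage=40, read_len=100, seed=20)
hist = count_kmers(reads, k=17)
est = estimate_genome_size(hist)

print(f"reads:                {len(reads)} x 100 bp (~40x)")
print(f"total 17-mers:        {hist.total_kmers}")
print(f"major-peak depth:     {est.peak_depth}")
print(f"estimated genome:     {est.genome_size_bp:,.0f} bp")
print(f"true genome:          {GENOME_LEN:,} bp "
      f"({100 * abs(est.genome_size_bp - GENOME_LEN) / GENOME_LEN:.1f}% error)")
print()
print("The estimate is (total k-mers) / (depth of the histogram's major")
print("peak): each genomic position contributes ~peak-depth k-mers, so the")
print("ratio recovers the number of distinct positions, i.e. genome size.")
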