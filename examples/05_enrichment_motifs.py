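"""GO enrichment with rich factors, and MYB-core promoter motif filtering.

Builds a small annotation universe with one genuinely enriched term, tests
it hypergeometrically with BH correction, then counts a MYB-core motif in
toy promoters and applies the "more than two elements" filter.
"""

from medsweep.enrich import (
    MotifSpec,
    count_motif_occurrences,
    filter_motif_targets,
    go_enrichment,
)

universe = {f"g{i}" for i in range(200)}
term2genes = {
    "GO:0009414 (response to water deprivation)": {f"g{i}" for i in range(0, 20)},
    "GO:0008150 (biological process)": {f"g{i}" for i in range(0, 200, 2)},
    "GO:0006979 (response to oxidative stress)": {f"g{i}" for i in range(100, 140)},
}
selected = {f"g{i}" for i in range(0, 15)}  # candidate genes from a scan
table = go_enrichment(selected, term2genes, universe)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))

motif = MotifSpec("CNGTT", both_strands=False)  # forward strand for clarity
promoters = {
    "gA": "AAACAGTTAAACCGTTAAACTGTTAAA",  # three MYB-core matches
    "gB": "AAACAGTTAAACCGTTAAAAAAAAAAA",  # two
    "gC": "A" * 30,                        # none
}
counts = {g: count_motif_occurrences(s, motif) for g, s in promoters.items()}
kept = filter_motif_targets(counts, min_count=2, strict_greater=True)
print(f"\nMYB-core (CNGTT) counts: {counts}")
print(f"genes with more than two elements: {sorted(kept)}")
print()
print("The rich factor k/K is the fraction of a term's genes that were")
print("selected; low BH-adjusted p plus high rich factor marks terms that")
print("characterize the candidate set. The motif filter keeps genes whose")
print("promoter carries >2 MYB-core elements - putative MYB targets.")
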