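"""Candidate-variant prioritization in the refined critical interval.

Applies GQ masking, panel association, conservation and gene-context
filters, then annotates the surviving missense change.
"""

from cranioscan.haplotypes import Interval
from cranioscan.simulate import SimConfig, simulate_resequencing_panel
from cranioscan.variants import (annotate_codon_change, combine_filters,
                                 conservation_filter, gene_context_filter,
                                 mask_gq, variant_assoc)

panel = simulate_resequencing_panel(SimConfig(seed=1))
records = panel.records
print(f"panel: {len(panel.sample_names)} genomes, {len(records)} variants")

_, n_masked = mask_gq(records, threshold=8)
print(f"genotype calls masked at GQ < 8: {n_masked}")

variant_assoc(records, panel.phenotypes, panel.sample_names,
              exclude=[panel.truth["outlier"]], tail=0.05)
conservation_filter(records, min_score=0.7)
gene_context_filter(records, panel.gene_models, splice_window=20)

refined = Interval(panel.interval.chrom, panel.interval.start,
                   panel.truth["breakpoint_pos"],
                   provenance="breakpoint-refined")
_, counts = combine_filters(records, refined)
print(f"variants in the refined interval: {counts['in_interval']}")
print(f"  conserved (phastCons-like >= 0.7): {counts['conserved']}")
print(f"  associated (smallest 5% of p):     {counts['associated']}")
print(f"  exonic:                            {counts['in_exon']}")
print(f"  near a splice junction (<=20 bp):  {counts['near_splice']}")
print(f"variants of interest (union):        {counts['of_interest']}")

causal = next(r for r in records if r.pos == panel.truth["causal_pos"])
cons = annotate_codon_change(panel.gene_models[0],
                             panel.cds_sequences["geneA"],
                             causal.pos, causal.alt)
print(f"planted causal variant {causal.chrom}:{causal.pos} "
      f"{causal.ref}>{causal.alt}: {cons.kind} {cons.notation} "
      f"({cons.codon_ref}->{cons.codon_alt}), retained = {causal.of_interest}")
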