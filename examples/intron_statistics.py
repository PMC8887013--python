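"""Extract introns from a synthetic annotated genome and summarize them.

Generates 500 genes whose intron counts are Poisson(7.43) with boundary
classes drawn at the canonical frequencies, then recovers density and
splice-boundary fractions from the FASTA + gene models alone.
"""
from orgatlas import (
    SimConfig,
    extract_introns,
    generate_synthetic_gene_models,
    summarize_intron_stats,
)

config = SimConfig(seed=42, n_genes=500)
genome, models, truth = generate_synthetic_gene_models(config)
introns = extract_introns(models, genome)
summary = summarize_intron_stats(introns, models, "unique_introns_per_gene")

print(f"genes:          {summary.genes_considered}")
print(f"introns:        {summary.total_introns}")
print(f"density:        {summary.density:.2f} introns/gene")
for cls, frac in summary.class_fractions.items():
    print(f"  {cls:<6} {frac:7.2%}")
print(f"exact recovery of planted introns: {introns == truth.introns}")
print()
print("Density should sit near the generating mean of 7.43 introns/gene and")
print("the GT-AG fraction near 98.41% — the splice-boundary spectrum typical")
print("of a spliceosomal genome; donor/acceptor dinucleotides are read in")
print("transcription orientation, so minus-strand genes need no special care.")
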