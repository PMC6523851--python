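"""Generate a synthetic host-microbiome study with planted ground truth.

The bundle mirrors the inputs of a four-arm 16S + transcriptome study:
an OTU count table with taxonomy, gene content + 16S copy numbers, a
pathway membership file, log2 host expression, a gene->KO map and the
sample design.  Three pathways are planted as "cassettes" whose KOs are
carried only by dedicated OTUs and targeted by dedicated host genes.
"""

from komix import generate_study

bundle = generate_study(seed=42)

print(f"OTU table:     {bundle.otu_table.shape} (features x samples)")
print(f"expression:    {bundle.expression.shape}")
print(f"gene content:  {len(bundle.gene_content.otu_ids)} OTUs x "
      f"{len(bundle.gene_content.ko_ids)} KOs")
print(f"pathways:      {len(bundle.pathway_db)}")
print(f"contrasts:     {bundle.design.contrasts}")
print()
print("planted pathways (pathway, comparison, direction):")
for pid, comp, direction in bundle.truth.planted_pathways:
    genera = ", ".join(bundle.truth.cassette_genera[pid])
    print(f"  {pid}: {comp} {direction}; cassette genera: {genera}")
# Each planted pathway must later surface in the joint enrichment of its
# comparison, and its deconvolution must name exactly these genera.
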