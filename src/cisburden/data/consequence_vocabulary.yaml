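# Sequence-Ontology consequence term -> classification.
# top_level: coding | noncoding
# subclass (coding):    missense | stop_gained | frameshift | splice_related | other_coding
# subclass (noncoding): utr | regulatory_region | splice_region | tfbs | intronic |
#                       intergenic | other_noncoding
#
# Splice acceptor/donor variants disrupt the coding transcript and sit under
# coding:splice_related; splice_region_variant is the milder, noncoding
# splice_region annotation.  Edit and pass via configuration to override.
missense_variant: {top_level: coding, subclass: missense}
stop_gained: {top_level: coding, subclass: stop_gained}
frameshift_variant: {top_level: coding, subclass: frameshift}
splice_acceptor_variant: {top_level: coding, subclass: splice_related}
splice_donor_variant: {top_level: coding, subclass: splice_related}
stop_lost: {top_level: coding, subclass: other_coding}
start_lost: {top_level: coding, subclass: other_coding}
inframe_insertion: {top_level: coding, subclass: other_coding}
inframe_deletion: {top_level: coding, subclass: other_coding}
synonymous_variant: {top_level: coding, subclass: other_coding}
stop_retained_variant: {top_level: coding, subclass: other_coding}
coding_sequence_variant: {top_level: coding, subclass: other_coding}
protein_altering_variant: {top_level: coding, subclass: other_coding}
start_retained_variant: {top_level: coding, subclass: other_coding}
3_prime_UTR_variant: {top_level: noncoding, subclass: utr}
5_prime_UTR_variant: {top_level: noncoding, subclass: utr}
splice_region_variant: {top_level: noncoding, subclass: splice_region}
regulatory_region_variant: {top_level: noncoding, subclass: regulatory_region}
TF_binding_site_variant: {top_level: noncoding, subclass: tfbs}
intron_variant: {top_level: noncoding, subclass: intronic}
intergenic_variant: {top_level: noncoding, subclass: intergenic}
upstream_gene_variant: {top_level: noncoding, subclass: other_noncoding}
downstream_gene_variant: {top_level: noncoding, subclass: other_noncoding}
non_coding_transcript_variant: {top_level: noncoding, subclass: other_noncoding}
non_coding_transcript_exon_variant: {top_level: noncoding, subclass: other_noncoding}
NMD_transcript_variant: {top_level: noncoding, subclass: other_noncoding}
mature_miRNA_variant: {top_level: noncoding, subclass: other_noncoding}
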