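# Starting-point pathway -> functional module map.
#
# Keys are exact pathway/set ids, or case-insensitive substrings matched
# against pathway display names.  Values must be one of:
#   immune | metabolic | endocrine | signal_transduction_cellular_regulation
# Module membership reflects curation; copy this file and edit it to
# encode your own grouping of enriched pathways into higher-order themes.
immun: immune
cytokine: immune
chemokine: immune
complement: immune
toll-like receptor: immune
nod-like receptor: immune
t cell receptor: immune
b cell receptor: immune
metabol: metabolic
biosynthesis: metabolic
degradation: metabolic
cytochrome p450: metabolic
glycolysis: metabolic
oxidative phosphorylation: metabolic
fatty acid: metabolic
endocrine: endocrine
hormone: endocrine
steroid: endocrine
thyroid: endocrine
insulin: endocrine
parathyroid: endocrine
signaling: signal_transduction_cellular_regulation
signal transduction: signal_transduction_cellular_regulation
cell cycle: signal_transduction_cellular_regulation
apoptosis: signal_transduction_cellular_regulation
mapk: signal_transduction_cellular_regulation
pi3k-akt: signal_transduction_cellular_regulation
calcium: signal_transduction_cellular_regulation
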