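# Variant-class severity map: 1 = silent, 2 = moderate, 3 = damaging.
# Keys are matched case-insensitively after stripping whitespace; edit or
# replace this file (pass severity_map=) to use an alternative mapping.
silent: 1
synonymous: 1
silent_mutation: 1
missense: 2
missense_mutation: 2
in_frame_del: 2
in_frame_ins: 2
splice_region: 2
nonsense: 3
nonsense_mutation: 3
frameshift: 3
frame_shift_del: 3
frame_shift_ins: 3
splice_site: 3
start_codon_del: 3
start_codon_snp: 3
stop_codon_del: 3
nonstop_mutation: 3
translation_start_site: 3
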