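# Full-scale run; QTL merging at the permissive LD threshold
# (markers with LD >= 0.1 treated as linked into one QTL region).
seed: 1
n_lines: 1135
n_markers: 4255
ssd_generations: 8
r2_link: 0.1
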