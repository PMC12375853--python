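# Full-scale run; QTL merging at the conservative LD threshold.
seed: 1
n_lines: 1135
n_markers: 4255
ssd_generations: 8
r2_link: 0.5
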