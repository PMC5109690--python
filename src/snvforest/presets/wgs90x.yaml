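# Whole-genome regime: 90X mean depth, lower per-base error.
n_sites: 20000
mean_depth_tumor: 90.0
mean_depth_normal: 90.0
error_rate: 0.005
n_somatic: 20
somatic_vaf_range: [0.16, 0.58]
n_germline: 50
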