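# Training regime sized to yield roughly 250 true-positive and 30,000
# false-positive candidates after screening (error-prone low-pass data).
n_sites: 53000
mean_depth_tumor: 30.0
mean_depth_normal: 30.0
error_rate: 0.03
n_somatic: 250
somatic_vaf_range: [0.16, 0.58]
n_germline: 150
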