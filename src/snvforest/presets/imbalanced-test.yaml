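# Severely imbalanced calling scenario: 100k sites at 30X with 50 planted
# somatic SNVs spanning clonal and subclonal VAFs.
n_sites: 100000
mean_depth_tumor: 30.0
mean_depth_normal: 30.0
error_rate: 0.01
n_somatic: 50
somatic_vaf_range: [0.10, 0.60]
n_germline: 100
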