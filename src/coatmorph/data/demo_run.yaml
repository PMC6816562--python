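# Demonstration pipeline configuration.  Relative paths resolve against this
# file's directory.  Fault probabilities are computed from the fixed demo
# frequency table so the four worked-example values are reproduced exactly.
cohort_spec: demo_cohort.yaml
fault_frequencies: demo_frequencies.csv
n_breeds: 30
seed: 20191028
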