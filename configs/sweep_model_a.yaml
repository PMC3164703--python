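# Robustness sweep of the minimal model over its default affinity pairs,
# two orders of magnitude around the reference values.
variant: A
scenario: {fold_range: 100.0, n_grid: 21}
seed: 0
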