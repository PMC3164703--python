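# Robustness sweep of the full model: the Hdac/Factor-A gate (phi)
# against the other Sox10-Mitfa module affinities.
variant: C
scenario: {fold_range: 100.0, n_grid: 21}
seed: 0
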