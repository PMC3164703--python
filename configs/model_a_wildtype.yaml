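# Minimal feed-forward repression circuit (variant A), wild type.
# Sox10 stays on at steady state: the variant fails the behaviour criteria.
variant: A
genotype: wt
integration: {t0: 0.0, t1: 96.0, dt: 0.01}
seed: 0
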