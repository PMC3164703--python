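# Intermediate model (variant B): Factor-Y feedback and the Hdac gate on
# the Mitfa->sox10 term only.  Persistent Factor-A input keeps sox10 on.
variant: B
genotype: wt
integration: {t0: 0.0, t1: 96.0, dt: 0.01}
seed: 0
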