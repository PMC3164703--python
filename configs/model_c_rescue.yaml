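# Transient exogenous Mitfa in the sox10 mutant: a plateau ten-fold above
# the Mitfa threshold M* for ten hours drives the bistable switch on.
variant: C
genotype: sox10_null
scenario:
  pulse: {amplitude: 0.1, t_on: 24.0, t_off: 34.0, decay_rate: 5.0}
seed: 0
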