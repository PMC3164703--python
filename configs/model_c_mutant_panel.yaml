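# Full-model mutant panel: run with `melgrn panel --config ...`.
# The sox10-null, mitfa-null and double-null genotypes are built in.
variant: C
integration: {t0: 0.0, t1: 96.0, dt: 0.01}
seed: 0
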