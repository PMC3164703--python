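# Full model (variant C), wild type: the reference simulation.
variant: C
genotype: wt
integration: {t0: 0.0, t1: 96.0, dt: 0.01}
thresholds: {theta_det: 0.01, r_min: 5.0, t_late: 60.0}
seed: 0
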