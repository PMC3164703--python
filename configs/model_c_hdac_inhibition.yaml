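# Chemical Hdac inhibition from 24 to 48 hpf (treated vs control,
# wild type and mitfa mutant).
variant: C
scenario:
  window: [24.0, 48.0]
seed: 0
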