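# Desk-scale configuration: full-scale architecture defaults are kernel 18
# with 256 neurons; 32 neurons trains in minutes on one CPU and loses
# little on composition-dominated corpora.
model:
  kernel_size: 18
  n_neurons: 32
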