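# Desk-scale (0.1x) incremental-reference-panel experiment.
# Panel sizes derive from the full-scale ratios (661:503:347 base panel,
# 300 targets) times `scale`; all other keys have defaults.
seed: 1
scale: 0.1
added_sizes: [0, 20, 50, 100]
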