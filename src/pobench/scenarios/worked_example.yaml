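name: worked_example
rows: 2
cols: 2
tox_probs:
- [0.1, 0.3]
- [0.2, 0.4]
gamma: 0.2
targets:
- [2, 1]
n: 10
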