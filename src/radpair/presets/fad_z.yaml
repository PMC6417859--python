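name: FAD-Z
nuclei:
  - {label: N5, spin: 1, coupling_uT: 523.0, electron: A}
  - {label: N10, spin: 1, coupling_uT: 189.0, electron: A}
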