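name: 1d-simple
input_form: 1d
modules:
- branches:
  - kernel:
    - 7
    out: 24
  pool:
  - 2
- branches:
  - kernel:
    - 7
    out: 72
  pool:
  - 2
- branches:
  - kernel:
    - 7
    out: 72
  pool:
  - 6
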