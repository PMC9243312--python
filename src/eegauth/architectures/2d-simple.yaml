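name: 2d-simple
input_form: 2d
modules:
- branches:
  - kernel:
    - 9
    - 7
    out: 24
  pool:
  - 2
  - 2
- branches:
  - kernel:
    - 12
    - 8
    out: 24
  pool:
  - 4
  - 4
- branches:
  - kernel:
    - 6
    - 4
    out: 24
  pool:
  - 2
  - 2
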