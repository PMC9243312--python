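name: 3d-simple
input_form: 3d
modules:
- branches:
  - kernel:
    - 5
    - 9
    - 7
    out: 24
  pool:
  - 1
  - 2
  - 2
- branches:
  - kernel:
    - 7
    - 12
    - 8
    out: 72
  pool:
  - 1
  - 4
  - 4
- branches:
  - kernel:
    - 6
    - 6
    - 4
    out: 72
  pool:
  - 1
  - 1
  - 1
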