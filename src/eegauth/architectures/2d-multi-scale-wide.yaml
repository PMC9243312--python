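name: 2d-multi-scale-wide
input_form: 2d
modules:
- reduce: 24
  branches:
  - kernel:
    - 3
    - 7
    out: 24
  - kernel:
    - 3
    - 5
    out: 24
  - kernel:
    - 3
    - 3
    out: 24
  pool:
  - 2
  - 2
- reduce: 72
  branches:
  - kernel:
    - 3
    - 7
    out: 72
  - kernel:
    - 3
    - 5
    out: 72
  - kernel:
    - 3
    - 3
    out: 72
  pool:
  - 2
  - 2
- reduce: 72
  branches:
  - kernel:
    - 3
    - 7
    out: 72
  - kernel:
    - 3
    - 5
    out: 72
  - kernel:
    - 3
    - 3
    out: 72
  pool:
  - 5
  - 5
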