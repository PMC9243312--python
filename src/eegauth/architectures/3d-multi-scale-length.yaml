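name: 3d-multi-scale-length
input_form: 3d
modules:
- reduce: 24
  branches:
  - kernel:
    - 6
    - 7
    - 3
    out: 24
  - kernel:
    - 6
    - 5
    - 3
    out: 24
  - kernel:
    - 6
    - 3
    - 3
    out: 24
  pool:
  - 1
  - 2
  - 2
- reduce: 72
  branches:
  - kernel:
    - 6
    - 7
    - 3
    out: 72
  - kernel:
    - 6
    - 5
    - 3
    out: 72
  - kernel:
    - 6
    - 3
    - 3
    out: 72
  pool:
  - 1
  - 2
  - 2
- reduce: 72
  branches:
  - kernel:
    - 6
    - 7
    - 3
    out: 72
  - kernel:
    - 6
    - 5
    - 3
    out: 72
  - kernel:
    - 6
    - 3
    - 3
    out: 72
  pool:
  - 1
  - 5
  - 5
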