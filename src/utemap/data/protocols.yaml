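# Default two-measurement UTE protocol (3 T, 123.256 MHz).
# Times in ms, flip angles in degrees.
measurement1:
  tr: 4.92
  fa: 3.0
  tes: [0.03]
  label: "UTE scan 1: single ultrashort echo, minimized T1 weighting"
measurement2:
  tr: 9.24
  fa: 11.0
  tes: [0.03, 2.46, 4.92]
  label: "UTE scan 2: dual-echo T2* mapping at the Ernst angle for T1 ~ 500 ms"
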