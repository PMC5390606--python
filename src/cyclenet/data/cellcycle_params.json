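{
  "r11": -1.6525,
  "r12": 0.56,
  "r13": 1.22,
  "r21": 0.21,
  "r22": -1.72,
  "r23": 0.85,
  "r24": 0.3919,
  "r31": 0.32,
  "r32": -1.65,
  "r33": 0.45,
  "r34": 0.38,
  "r41": 0.31,
  "r42": 0.23,
  "r43": -1.62,
  "r44": 0.16,
  "r51": 0.24,
  "r52": 0.12,
  "r53": 0.11,
  "r54": -1.9
}
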