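CCNA1
CCNB1
CCND1
CCNE1
CDH1
CDT1
CDKN1B
CDK1
CDK2
CDK4
CDK6
TP53
GMNN
SKP2
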