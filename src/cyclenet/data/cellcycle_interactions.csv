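CCNA1,CCNB1,CCND1,CCNE1,CDH1,CDT1,CDKN1B,CDK1,CDK2,CDK4,CDK6,TP53,GMNN,SKP2
O,O,O,O,Y,Y,Y,Y,Y,O,O,O,O,Y
O,O,O,Y,Y,Y,X/Y,X/Y,Y,O,O,X,O,Y
X,O,X/Y,X,X,O,X/Y,Y,X/Y,X/Y,X/Y,X/Y,O,Y
O,X/Y,O,X,O,O,Y,X/Y,X/Y,X/Y,X/Y,X,O,Y
Y,Y,O,O,X/Y,O,O,O,Y,O,O,Y,Y,Y
Y,Y,O,Y,O,O,O,Y,Y,O,Y,O,O,Y
X/Y,Y,X/Y,X/Y,O,O,X/Y,X/Y,X/Y,X/Y,X/Y,O,O,Y
Y,X/Y,Y,Y,O,X/Y,X/Y,X/Y,X/Y,X/Y,O,X/Y,Y,Y
O,Y,X/Y,Y,Y,X/Y,X/Y,O,X/Y,X/Y,Y,O,Y,X/Y
O,O,Y,X/Y,O,X/Y,Y,X/Y,X/Y,X/Y,X/Y,Y,O,O
O,O,Y,Y,O,O,X/Y,O,X/Y,X/Y,X/Y,O,O,O
O,X,X/Y,X,X/Y,X,X,X/Y,X/Y,X/Y,O,X/Y,X,O
O,O,O,O,X/Y,X/Y,O,Y,Y,O,O,X,Y,Y
Y,Y,Y,X/Y,Y,X/Y,X/Y,Y,X/Y,O,O,O,Y,X/Y
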