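Ser203
His447
Glu334
Trp86
Gly121
Gly122
Tyr124
Ser125
Glu202
Ala204
Trp286
Phe295
Phe297
Tyr337
Phe338
Tyr341
Asp74
Tyr72
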