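Gli2
Tcf7
Runx2
Sox9
MEF2C
STAT1
ATF2
NFκB
CCND1
Dlx5
Ets1
δ-EF1
HIF-2α
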