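	Gli2	Tcf7	Runx2	Sox9	MEF2C	STAT1	ATF2	NFκB	CCND1	Dlx5	Ets1	δ-EF1	HIF-2α
Gli2	0	0	0	0	0	0	0	0	0	0	0	0	0
Tcf7	0	0	0	0	0	0	0	0	0	0	0	0	0
Runx2	0	0	0	-1	1	0	0	0	0	0	0	0	0
Sox9	0	0	-1	0	0	0	0	0	0	0	0	0	0
MEF2C	0	0	1	0	0	0	0	0	0	1	0	0	0
STAT1	0	0	0	0	0	0	0	0	0	0	0	0	0
ATF2	0	0	0	0	0	0	0	0	1	0	0	0	0
NFκB	0	0	0	1	0	0	0	0	0	0	0	0	1
CCND1	0	0	0	0	0	0	0	0	0	0	0	0	0
Dlx5	0	0	0	0	0	0	0	0	0	0	0	0	0
Ets1	0	0	0	0	0	0	0	0	0	0	0	1	0
δ-EF1	0	0	0	0	0	0	0	0	0	0	0	0	0
HIF-2α	0	0	0	0	0	0	0	0	0	0	0	0	0
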