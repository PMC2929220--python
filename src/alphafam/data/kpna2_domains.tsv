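# Estimated domain annotation for human KPNA2 (529 aa).
# IBB and ARM-repeat boundaries are approximate (the published family
# figure shows them only graphically); intervals are 1-based inclusive
# on the ungapped KPNA2 sequence.
KPNA2	IBB	1	95
KPNA2	ARM1	100	141
KPNA2	ARM2	142	183
KPNA2	ARM3	184	225
KPNA2	ARM4	226	267
KPNA2	ARM5	268	309
KPNA2	ARM6	310	351
KPNA2	ARM7	352	393
KPNA2	ARM8	394	435
KPNA2	ARM9	436	477
KPNA2	ARM10	478	519
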