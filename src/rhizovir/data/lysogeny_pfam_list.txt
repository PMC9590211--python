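# Pfam accessions for lysogeny-associated proteins
# (transposase, integrase, excisionase, resolvase, recombinase)
PF07508
PF00589
PF01609
PF03184
PF02914
PF01797
PF04986
PF00665
PF07825
PF00239
PF13009
PF16795
PF01526
PF03400
PF01610
PF03050
PF04693
PF07592
PF12762
PF13359
PF13586
PF13610
PF13612
PF13701
PF13737
PF13751
PF13808
PF13843
PF13358
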