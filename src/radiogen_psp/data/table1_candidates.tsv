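coverage_level	threshold_label	genes
0.8	>22	AP1M1;C19orf66;IFI44L;IFIT3;IRF9;OAS3;TULP3;USP18;DYNLL2;TAS2R19;APBB3;FAM122C;IFI6;MED12;MGLL;BAZ2A;ERCC1;PHF8;RAD9A;XRCC1;ATF7;C17orf65;C2CD3;DNAJC9;FMR1;FOXJ2;KDM5A;KIAA0753;MRI1;MRPS6;RAB8A;TAB3;TCTN2
0.9	>24	AP1M1;C19orf66;IFI44L;IRF9;TULP3;DYNLL2;APBB3;IFI6;MED12;BAZ2A;ERCC1;PHF8;XRCC1;ATF7;C2CD3;DNAJC9;MRPS6;RAB8A;TAB3;TCTN2
1.0	==27	AP1M1;C19orf66;IFI44L;IRF9;TULP3;DYNLL2;APBB3;IFI6;XRCC1;ATF7;DNAJC9;MRPS6
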