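>ebox_cacgtg bHLH
0.050	0.850	0.050	0.050	0.050	0.050
0.850	0.050	0.850	0.050	0.050	0.050
0.050	0.050	0.050	0.850	0.050	0.850
0.050	0.050	0.050	0.050	0.850	0.050
>ebox_cagctg bHLH
0.050	0.850	0.050	0.050	0.050	0.050
0.850	0.050	0.050	0.850	0.050	0.050
0.050	0.050	0.850	0.050	0.050	0.850
0.050	0.050	0.050	0.050	0.850	0.050
>fkh_tgtttac forkhead
0.050	0.050	0.050	0.050	0.050	0.850	0.050
0.050	0.050	0.050	0.050	0.050	0.050	0.850
0.050	0.850	0.050	0.050	0.050	0.050	0.050
0.850	0.050	0.850	0.850	0.850	0.050	0.050
>fkh_gtaaaca forkhead
0.050	0.050	0.850	0.850	0.850	0.050	0.850
0.050	0.050	0.050	0.050	0.050	0.850	0.050
0.850	0.050	0.050	0.050	0.050	0.050	0.050
0.050	0.850	0.050	0.050	0.050	0.050	0.050
>hth_taatta HTH
0.050	0.850	0.850	0.050	0.050	0.850
0.050	0.050	0.050	0.050	0.050	0.050
0.050	0.050	0.050	0.050	0.050	0.050
0.850	0.050	0.050	0.850	0.850	0.050
>hth_taatcc HTH
0.050	0.850	0.850	0.050	0.050	0.050
0.050	0.050	0.050	0.050	0.850	0.850
0.050	0.050	0.050	0.050	0.050	0.050
0.850	0.050	0.050	0.850	0.050	0.050
>mads_carg MADS
0.050	0.050	0.850	0.050	0.850	0.050	0.850	0.050	0.050	0.050
0.850	0.850	0.050	0.050	0.050	0.050	0.050	0.050	0.050	0.050
0.050	0.050	0.050	0.050	0.050	0.050	0.050	0.050	0.850	0.850
0.050	0.050	0.050	0.850	0.050	0.850	0.050	0.850	0.050	0.050
>bzip_tgacgtca bZIP
0.050	0.050	0.850	0.050	0.050	0.050	0.050	0.850
0.050	0.050	0.050	0.850	0.050	0.050	0.850	0.050
0.050	0.850	0.050	0.050	0.850	0.050	0.050	0.050
0.850	0.050	0.050	0.050	0.050	0.850	0.050	0.050
>nr_aggtca NR
0.850	0.050	0.050	0.050	0.050	0.850
0.050	0.050	0.050	0.050	0.850	0.050
0.050	0.850	0.850	0.050	0.050	0.050
0.050	0.050	0.050	0.850	0.050	0.050
>gata_agataa GATA
0.850	0.050	0.850	0.050	0.850	0.850
0.050	0.050	0.050	0.050	0.050	0.050
0.050	0.850	0.050	0.050	0.050	0.050
0.050	0.050	0.050	0.850	0.050	0.050
>ets_ccggaagt ETS
0.050	0.050	0.050	0.050	0.850	0.850	0.050	0.050
0.850	0.850	0.050	0.050	0.050	0.050	0.050	0.050
0.050	0.050	0.850	0.850	0.050	0.050	0.850	0.050
0.050	0.050	0.050	0.050	0.050	0.050	0.050	0.850
>znf_gggcgggg C2H2-ZF
0.050	0.050	0.050	0.050	0.050	0.050	0.050	0.050
0.050	0.050	0.050	0.850	0.050	0.050	0.050	0.050
0.850	0.850	0.850	0.050	0.850	0.850	0.850	0.850
0.050	0.050	0.050	0.050	0.050	0.050	0.050	0.050
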