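((((((melanogaster:5.4,(simulans:2.3,sechellia:2.3)n_simsech:3.1)n_melsimsech:7.4,(yakuba:10.4,erecta:10.4)n_yakere:2.4)n_melgrp:31.4,ananassae:44.2)n_melana:10.7,pseudoobscura:54.9)n_melpse:7.3,willistoni:62.2)n_soph:0.7,((mojavensis:32.1,virilis:32.1)n_mojvir:4.5,grimshawi:36.6)n_dros:26.3)root;
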