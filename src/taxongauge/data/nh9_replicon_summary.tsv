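replicon	accession	length_bp	gc_percent	cds_count
Chromosome 1	CP017757	4347557	65.8	3912
Chromosome 2	CP017758	3395604	65.5	2932
pENH91	CP017760	77172	64.2	78
pENH92	CP017759	426602	61.8	368
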