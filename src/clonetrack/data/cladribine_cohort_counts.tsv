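patient	timepoint	sorted_cells	unique_sequences	sequences_annotated
CLAD1	B	193991	27529	22691
CLAD2	B	208036	30760	27239
CLAD3	B	280632	67212	50407
CLAD4	B	80298	44866	35761
CLAD5	B	308219	48188	30648
CLAD6	B	200612	72155	62545
CLAD7	B	123159	61585	47015
CLAD8	B	294599	51004	31714
CLAD1	6M	268127	37554	31930
CLAD2	6M	425004	72975	52052
CLAD3	6M	179550	58008	37343
CLAD4	6M	78145	40667	32298
CLAD5	6M	194339	42596	27474
CLAD6	6M	138083	91769	76794
CLAD7	6M	64974	47139	30738
CLAD8	6M	107631	44271	32852
CLAD1	12M	581877	61332	42056
CLAD2	12M	1017071	61944	44995
CLAD3	12M	102497	57953	39613
CLAD4	12M	54645	35811	24870
CLAD5	12M	251382	40801	27025
CLAD6	12M	359947	93580	79131
CLAD7	12M	125506	53373	40070
CLAD8	12M	124121	49833	32090
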