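# Synthetic stand-in gene lists for signature scoring.
# Benchmark signatures (TIDE/TIS/IPS/IFNG) are configuration-level gene-set
# stand-ins defined over the synthetic generator's gene universe; they are
# NOT the published gene definitions.
signature	gene	direction
HOT	HOT01	1
HOT	HOT02	1
HOT	HOT03	1
HOT	HOT04	1
HOT	HOT05	1
HOT	HOT06	1
HOT	HOT07	1
HOT	HOT08	1
HOT	HOT09	1
HOT	HOT10	1
HOT	HOT11	1
HOT	HOT12	1
HOT	HOT13	1
HOT	HOT14	1
HOT	HOT15	1
HOT	HOT16	1
HOT	HOT17	1
HOT	HOT18	1
HOT	HOT19	1
HOT	HOT20	1
HOT	HOT21	1
HOT	HOT22	1
HOT	HOT23	1
HOT	HOT24	1
HOT	HOT25	1
HOT	HOT26	1
HOT	HOT27	1
IFNG	HOT01	1
IFNG	HOT02	1
IFNG	HOT03	1
IFNG	HOT04	1
IFNG	HOT05	1
IFNG	HOT06	1
TIS	HOT07	1
TIS	HOT08	1
TIS	HOT09	1
TIS	HOT10	1
TIS	HOT11	1
TIS	HOT12	1
TIS	HOT13	1
TIS	HOT14	1
TIS	HOT15	1
TIS	HOT16	1
TIS	HOT17	1
TIS	HOT18	1
TIS	G0001	1
TIS	G0002	1
TIS	G0003	1
TIS	G0004	1
TIS	G0005	1
TIS	G0006	1
IPS	HOT19	1
IPS	HOT20	1
IPS	HOT21	1
IPS	HOT22	1
IPS	HOT23	1
IPS	HOT24	1
IPS	HOT25	1
IPS	HOT26	1
IPS	HOT27	1
IPS	G0007	1
IPS	G0008	-1
IPS	G0009	1
IPS	G0010	-1
IPS	G0011	1
IPS	G0012	-1
TIDE	G0013	-1
TIDE	G0014	1
TIDE	G0015	1
TIDE	G0016	-1
TIDE	G0017	1
TIDE	G0018	1
TIDE	G0019	-1
TIDE	G0020	1
TIDE	G0021	1
TIDE	G0022	-1
TIDE	G0023	1
TIDE	G0024	1
TIDE	G0025	-1
TIDE	G0026	1
TIDE	G0027	1
TIDE	G0028	-1
TIDE	G0029	1
TIDE	G0030	1
TIDE	G0031	-1
TIDE	G0032	1
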