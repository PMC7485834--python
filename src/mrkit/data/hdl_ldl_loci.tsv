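locus_name	chrom	start	end	trait
ABCA1	9	107543283	107690527	hdl
APOA4-APOC3-APOA1	11	116691418	116708338	hdl
APOE-APOC1-APOC4-APOC2	19	45409039	45452822	hdl
CETP	16	56995762	57017757	hdl
LCAT	16	67973788	67978017	hdl
LIPC	15	58702768	58861151	hdl
LIPG	18	47088627	47120147	hdl
PLTP	20	44527422	44541688	hdl
SCARB1	12	125262177	125348259	hdl
APOB	2	21224301	21266945	ldl
HMGCR	5	74632154	74657929	ldl
LDLR	19	11200038	11244506	ldl
LPA	6	160952515	161087407	ldl
MYLIP	6	16129086	16148479	ldl
NPC1L1	7	44552134	44580914	ldl
PCSK9	1	55505221	55530525	ldl
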