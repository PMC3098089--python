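!gaf-version: 2.0
UniProtKB	P00001	chick1		GO:0007595	GO_REF:0000001	IEA		P			protein	taxon:9031	20100101	UniProtKB		
UniProtKB	P00002	platy1		GO:0007595	GO_REF:0000001	IDA		P			protein	taxon:9258	20100101	UniProtKB		
UniProtKB	P00003	chick2		GO:1903487	GO_REF:0000001	IEA		P			protein	taxon:9031	20100101	UniProtKB		
UniProtKB	P00004	fly1		GO:0019684	GO_REF:0000001	IEA		P			protein	taxon:7227	20100101	UniProtKB		
TAIR	AT1G01	psb1		GO:0015979	GO_REF:0000001	IDA		P			protein	taxon:3702	20100101	TAIR		
UniProtKB	P00005	eug1		GO:0009762	GO_REF:0000001	ISS		P			protein	taxon:3039	20100101	UniProtKB		
TAIR	AT1G02	pck1		GO:0009762	GO_REF:0000001	IMP		P			protein	taxon:3702	20100101	TAIR		
SGD	S000001	sec1		GO:0030141	GO_REF:0000001	IDA		C			protein	taxon:4932	20100101	SGD		
UniProtKB	P00006	ust1		GO:0030141	GO_REF:0000001	ISS		C			protein	taxon:5270	20100101	UniProtKB		
PomBase	SPAC1	spb1		GO:0051300	GO_REF:0000001	IMP		P			protein	taxon:4896	20100101	PomBase		
EcoCyc	EG10001	ecn1		GO:0099999	GO_REF:0000001	IEA		P			protein	taxon:562	20100101	EcoCyc		
UniProtKB	P00007	bat1		GO:0030879	GO_REF:0000001	ISS		P			protein	taxon:568129	20100101	UniProtKB		
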