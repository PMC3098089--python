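db	db_object_id	db_object_symbol	go_id	go_name	evidence_code	aspect	taxon	constraint_kind	constraint_taxon	constraint_origin_class	inheritance_path
UniProtKB	P00001	chick1	GO:0007595	lactation	IEA	P	NCBITaxon:9031	only_in	NCBITaxon:40674	GO:0030879	GO:0007595>GO:0030879
UniProtKB	P00004	fly1	GO:0019684	photosynthesis, light reaction	IEA	P	NCBITaxon:7227	only_in	NCBITaxon_Union:0000021	GO:0015979	GO:0019684>GO:0015979
UniProtKB	P00005	eug1	GO:0009762	PEP carboxykinase C4 photosynthesis	ISS	P	NCBITaxon:3039	only_in	NCBITaxon:33090	GO:0009760	GO:0009762>GO:0009760
SGD	S000001	sec1	GO:0030141	secretory granule	IDA	C	NCBITaxon:4932	never_in	NCBITaxon:4890	GO:0030141	GO:0030141
EcoCyc	EG10001	ecn1	GO:0099999	nuclear translation	IEA	P	NCBITaxon:562	only_in	NCBITaxon:2759	GO:0005634	GO:0099999>GO:0005634
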