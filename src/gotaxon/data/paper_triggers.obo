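format-version: 1.2

[Term]
id: GO:0005634
name: nucleus
namespace: cellular_component
relationship: only_in_taxon NCBITaxon:2759

[Term]
id: GO:0009760
name: C4 photosynthesis
namespace: biological_process
relationship: only_in_taxon NCBITaxon:33090

[Term]
id: GO:0015979
name: photosynthesis
namespace: biological_process
relationship: only_in_taxon NCBITaxon_Union:0000021

[Term]
id: GO:0030141
name: secretory granule
namespace: cellular_component
relationship: never_in_taxon NCBITaxon:4890

[Term]
id: GO:0030879
name: mammary gland development
namespace: biological_process
relationship: only_in_taxon NCBITaxon:40674

[Term]
id: GO:0051300
name: spindle pole body organization
namespace: biological_process
relationship: only_in_taxon NCBITaxon:4751
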