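format-version: 1.2

[Term]
id: GO:0005575
name: cellular_component
namespace: cellular_component

[Term]
id: GO:0005634
name: nucleus
namespace: cellular_component
is_a: GO:0043231

[Term]
id: GO:0006412
name: translation
namespace: biological_process
is_a: GO:0008152

[Term]
id: GO:0006996
name: organelle organization
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0007595
name: lactation
namespace: biological_process
is_a: GO:0030879

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0008152
name: metabolic process
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0009760
name: C4 photosynthesis
namespace: biological_process
is_a: GO:0015979

[Term]
id: GO:0009762
name: PEP carboxykinase C4 photosynthesis
namespace: biological_process
is_a: GO:0009760

[Term]
id: GO:0015979
name: photosynthesis
namespace: biological_process
is_a: GO:0008152

[Term]
id: GO:0019684
name: photosynthesis, light reaction
namespace: biological_process
relationship: part_of GO:0015979

[Term]
id: GO:0030141
name: secretory granule
namespace: cellular_component
is_a: GO:0031410

[Term]
id: GO:0030879
name: mammary gland development
namespace: biological_process
is_a: GO:0048856

[Term]
id: GO:0031410
name: cytoplasmic vesicle
namespace: cellular_component
is_a: GO:0043226

[Term]
id: GO:0043226
name: organelle
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0043231
name: intracellular membrane-bounded organelle
namespace: cellular_component
is_a: GO:0043226

[Term]
id: GO:0048856
name: anatomical structure development
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0050789
name: regulation of biological process
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0051300
name: spindle pole body organization
namespace: biological_process
is_a: GO:0006996

[Term]
id: GO:0099999
name: nuclear translation
namespace: biological_process
is_a: GO:0006412
relationship: occurs_in GO:0005634

[Term]
id: GO:1903487
name: regulation of lactation
namespace: biological_process
is_a: GO:0050789
relationship: regulates GO:0007595
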