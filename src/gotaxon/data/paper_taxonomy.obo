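format-version: 1.2

[Term]
id: NCBITaxon:1
name: root
namespace: taxonomy

[Term]
id: NCBITaxon:131567
name: cellular organisms
namespace: taxonomy
is_a: NCBITaxon:1

[Term]
id: NCBITaxon:2
name: Bacteria
namespace: taxonomy
is_a: NCBITaxon:131567

[Term]
id: NCBITaxon:2157
name: Archaea
namespace: taxonomy
is_a: NCBITaxon:131567

[Term]
id: NCBITaxon:2759
name: Eukaryota
namespace: taxonomy
is_a: NCBITaxon:131567

[Term]
id: NCBITaxon:3039
name: Euglena gracilis
namespace: taxonomy
is_a: NCBITaxon:33682

[Term]
id: NCBITaxon:32525
name: Theria
namespace: taxonomy
is_a: NCBITaxon:40674

[Term]
id: NCBITaxon:33090
name: Viridiplantae
namespace: taxonomy
is_a: NCBITaxon:2759

[Term]
id: NCBITaxon:33208
name: Metazoa
namespace: taxonomy
is_a: NCBITaxon:2759

[Term]
id: NCBITaxon:33682
name: Euglenozoa
namespace: taxonomy
is_a: NCBITaxon:2759

[Term]
id: NCBITaxon:3702
name: Arabidopsis thaliana
namespace: taxonomy
is_a: NCBITaxon:33090

[Term]
id: NCBITaxon:40674
name: Mammalia
namespace: taxonomy
is_a: NCBITaxon:33208

[Term]
id: NCBITaxon:4751
name: Fungi
namespace: taxonomy
is_a: NCBITaxon:2759

[Term]
id: NCBITaxon:4890
name: Ascomycota
namespace: taxonomy
is_a: NCBITaxon:4751

[Term]
id: NCBITaxon:4896
name: Schizosaccharomyces pombe
namespace: taxonomy
is_a: NCBITaxon:4890

[Term]
id: NCBITaxon:4932
name: Saccharomyces cerevisiae
namespace: taxonomy
is_a: NCBITaxon:4890

[Term]
id: NCBITaxon:5204
name: Basidiomycota
namespace: taxonomy
is_a: NCBITaxon:4751

[Term]
id: NCBITaxon:5270
name: Ustilago maydis
namespace: taxonomy
is_a: NCBITaxon:5204

[Term]
id: NCBITaxon:562
name: Escherichia coli
namespace: taxonomy
is_a: NCBITaxon:2

[Term]
id: NCBITaxon:568129
name: Desmalopex leucopterus
namespace: taxonomy
is_a: NCBITaxon:32525

[Term]
id: NCBITaxon:7227
name: Drosophila melanogaster
namespace: taxonomy
is_a: NCBITaxon:33208

[Term]
id: NCBITaxon:8782
name: Aves
namespace: taxonomy
is_a: NCBITaxon:33208

[Term]
id: NCBITaxon:9031
name: Gallus gallus
namespace: taxonomy
is_a: NCBITaxon:8782

[Term]
id: NCBITaxon:9258
name: Ornithorhynchus anatinus
namespace: taxonomy
is_a: NCBITaxon:40674

[Term]
id: NCBITaxon_Union:0000021
name: Viridiplantae or Bacteria or Euglenozoa or Archaea
namespace: taxonomy
union_of: NCBITaxon:33090
union_of: NCBITaxon:2
union_of: NCBITaxon:33682
union_of: NCBITaxon:2157
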