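# Controlled vocabulary of PTM type labels, version 1.
#
# `types` maps each canonical label to the amino acids it is compatible
# with (null = any residue). `synonyms` maps source-catalog spellings to
# canonical labels; matching is case-insensitive after stripping
# non-alphanumeric characters. `nonenzymatic` lists labels deposited by
# direct chemistry rather than a writer enzyme; they are excluded from
# enzyme-pairing (E/ME) logic but still counted as modifications.
version: 1
types:
  phosphorylation: [S, T, Y, H]
  acetylation: [K]
  ubiquitination: [K]
  methylation: [K, R]
  sumoylation: [K]
  glycosylation: [N, S, T]
  succinylation: [K]
  malonylation: [K]
  citrullination: [R]
  hydroxylation: [P, K]
  nitrosylation: [C]
  palmitoylation: [C]
  myristoylation: [G]
  glutathionylation: [C]
  sulfenylation: [C]
  oxidation: null
  caspase_cleavage: [D]
  neddylation: [K]
synonyms:
  phospho: phosphorylation
  phosphorylated: phosphorylation
  p: phosphorylation
  acetyl: acetylation
  ac: acetylation
  ubiquitylation: ubiquitination
  ubiquitin: ubiquitination
  ub: ubiquitination
  methyl: methylation
  me: methylation
  monomethylation: methylation
  dimethylation: methylation
  trimethylation: methylation
  sumo: sumoylation
  sumoylated: sumoylation
  nglycosylation: glycosylation
  oglycosylation: glycosylation
  glcnac: glycosylation
  succinyl: succinylation
  malonyl: malonylation
  n6malonyllysine: malonylation
  snitrosylation: nitrosylation
  palmitoyl: palmitoylation
  myristoyl: myristoylation
  sulfenicacid: sulfenylation
  caspase: caspase_cleavage
  nedd8: neddylation
nonenzymatic:
  - oxidation
  - glutathionylation
  - sulfenylation
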