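# cassette

Comparative analysis of near-clonal symbiont genomes whose major
variable feature is secondary-metabolite gene-cluster cassettes.

The package covers the full desk-scale pipeline:

- **`cassette.simulate`** — generates a clonal genome population with
  the assumed statistical structure (≥97% backbone identity, clusters
  >99% identical when shared and present/absent at identical loci, a
  two-pathway pair whose central region diverges to 25–77% identity
  with per-genome recombination scars, ≤30 bp hypervariable core
  cassettes inside otherwise identical precursor genes, repeat
  elements, contig fragmentation with mate pairs) plus full
  ground-truth tables.
- **`cassette.synteny`** — anchor-based (seed–chain–extend) synteny
  blocks, length-weighted average nucleotide identity, synteny-break
  classification, contig-to-reference mapping, mate-pair order
  verification, and a tetranucleotide-composition contig classifier.
- **`cassette.variation`** — integration-locus occupancy calling from
  conserved flank anchors, windowed-identity crossover profiling with
  breakpoint localization, core-cassette extraction, and three-level
  variation classification (1 presence/absence, 2 internal function
  swap, 3 hypervariable cassette).
- **`cassette.pcr`** — dual presence/absence primer assay design,
  virtual PCR, mutual-exclusivity control enforcement, genotype-matrix
  assembly and a fixed-margin permutation co-occurrence test.
- **`cassette.chem`** — cyanobactin product chemistry: molecular
  formulas from core sequences and modification specs (macrocyclization,
  azoline/azole heterocycles, prenylation), protonated monoisotopic
  m/z, ppm errors, isoprene neutral-loss fragment ladders, candidate
  enumeration and observed-mass matching.
- **`cassette.pipeline` / `cassette.cli`** — end-to-end orchestration
  with a deterministic run manifest.

## CLI

```sh
cassette generate --seed 1 --out out/pop --fragment
cassette synteny --ref out/pop/P1.fasta --qry out/pop/P2.fasta --out out/syn
cassette variation --run-dir out/pop --out out/var
cassette pcr --run-dir out/pop --out out/pcr
cassette chem predict --core TTVTAC --pathway-class tru --observed 763.44345
cassette run-all --seed 1 --out out/run
```

`run-all` executes generate → synteny → variation → pcr → chem and
writes TSV/JSON artifacts plus `run_manifest.json`; re-running with the
same seed is byte-identical.

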