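# paracons

Paralog-conservation scoring and gene-family de novo mutation (DNM) burden
testing for protein-coding genes.

The pipeline:

1. **family_graph** — assemble gene families as connected components of a
   paralog-pair graph, then split each family into sub-families: two genes
   are linked when their Needleman–Wunsch global alignment (BLOSUM62, affine
   gaps) covers > 80 % of the longer sequence; sub-families are the
   connected components with ≥ 2 members.
2. **conservation** — score each alignment column with a physico-chemical
   conservation index in [0, 11] (count of residue properties uniformly
   present or absent; gap-free identity scores 11), project column scores
   onto each gene's residues, and z-normalize per gene (`para_zscore`).
   Residues with z > 0 are *paralog conserved*. The same code path serves
   ortholog alignments; `compare_conservation` reports Rand index, adjusted
   Rand and Pearson r between the two binary labelings.
3. **expectation** — per-gene expected DNM counts by consequence class from
   trinucleotide-context mutation rates summed over every possible coding
   substitution, scaled by 2 × n_trios. The missense expectation is split
   into conserved/non-conserved portions (proportional to site-class size,
   or by per-site rate summation).
4. **burden** — filter variants against a reference panel of standing
   variation, aggregate observed counts per sub-family and category
   (ptv, missense, missense_conserved, missense_nonconserved,
   missense_plus_ptv_conserved), and test enrichment with an upper-tail
   Poisson test computed in log space (stable to p ≪ 1e-400), Bonferroni
   corrected across categories × families. Candidate genes are flagged when
   they sit in an enriched family, carry a DNM, are brain-expressed
   (RPKM > 1) and constrained (pLI ≥ 0.9 or missense z > 3.09).
5. **annotation** — vt-style variant normalization (trim + left-align),
   per-variant para_zscore annotation, and per-protein track export with
   variant overlays (optional matplotlib plot).
6. **simulate** — synthetic block-structured gene families (conserved cores
   + variable linkers, CDS generated by synonymous codon choice) and
   Poisson-distributed DNM sets with a configurable conserved-site
   enrichment multiplier ρ; used throughout the test suite so no external
   data is needed.

## CLI

Everything is reachable through one entry point:

```sh
paracons build-families --pairs pairs.tsv --fasta proteins.fa --cutoff 0.8 --out fams/
paracons score-conservation --msa fams/fam.1.fa --out tracks.tsv
paracons compare-orthologs --paralog-tracks para.tsv --ortholog-tracks orth.tsv --out cmp.json
paracons expectations --cds cds.fa --rates rates.tsv --tracks tracks.tsv \
    --trios 10068 --mode proportional --out expectations.tsv
paracons enrich --dnms dnms.tsv --expectations expectations.tsv \
    --families fams/subfamilies.tsv --tracks tracks.tsv --panel panel.tsv --out results/
paracons annotate --dnms dnms.tsv --tracks tracks.tsv --out annotated.tsv
paracons export-track --gene KCNQ2 --tracks tracks.tsv --dnms dnms.tsv --out kcnq2.tsv
paracons simulate family --config sim.yaml --seed 17 --out simfam/
paracons simulate dnms --expectations expectations.tsv --tracks tracks.tsv \
    --rho 8 --seed 17 --out dnms.tsv
```

Formats: TSV with headers throughout; sequences as FASTA keyed by gene id;
pre-aligned FASTA (or Clustal) is accepted directly, and
`build-families --aligner-cmd 'mafft {input} > {output}'` can shell out to
an external aligner. The residue-property table used for column scoring
ships as an editable TSV (`src/paracons/data/amas_properties.tsv`) and is
echoed next to every scoring output for provenance. Genomic coordinates and
protein positions are 1-based.

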