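# clusterscope

Comparative analysis of biosynthetic gene clusters: delimit a conserved
cluster "core" against unrelated flanking DNA, reassemble split subcluster
contigs through a shared suffix–prefix overlap, triage alignment differences
into genuine inconsistencies vs gaps/ambiguities, and quantify cluster
relatedness through per-ortholog and concatenated protein identities.  A
ground-truth simulator generates every scenario the pipeline handles, so the
whole stack is testable offline.

## Modules

| module | purpose |
| --- | --- |
| `formats_io` | FASTA/GFF3/TSV I/O, CDS translation; 0-based half-open internally, converted only at the GFF3 boundary |
| `align_core` | global and free-end-gap pairwise alignment (Biopython Gotoh core, anchored seeding for long inputs), identity policies, IUPAC-aware column classification |
| `cluster_profile` | windowed identity profiles, core-boundary detection, inconsistency counting, marker differences, group-conserved diagnostic columns |
| `assembly_merge` | all-orientation suffix–prefix overlap search, provenance-tracked contig merging, reference verification |
| `orthologs` | reciprocal-best-hit ortholog mapping, gene-order collinearity, per-protein and concatenated identity matrices |
| `synthetic_data` | seeded generators for cluster genomes, diverged strains, overlap-split contigs, marker panels, planted-site alignments |
| `cli` | `clusterscope` command with `simulate / profile / boundaries / merge / orthologs / compare / report` subcommands |

## CLI quick start

```sh
# make a synthetic misassembly scenario with ground truth
clusterscope simulate --scenario ecd_hty_reassembly --seed 7 --out fixture/

# detect the contig overlap, merge, and verify against the reference
clusterscope merge \
  --contigs fixture/contigs/left.fasta --contigs fixture/contigs/right.fasta \
  --reference fixture/reference.fasta \
  --out merged.fasta --report report.tsv --bed provenance.bed

# windowed identity profile and core delimitation of two clusters
clusterscope profile    --a genomeA.fasta --b genomeB.fasta --out profile.tsv
clusterscope boundaries --a genomeA.fasta --b genomeB.fasta --out core.gff3

# ortholog table, collinearity and identity matrices
clusterscope orthologs --a-fasta a.fasta --a-gff a.gff3 \
                       --b-fasta b.fasta --b-gff b.gff3 --out-prefix orth

# chain profile + boundaries + orthologs, then summarize
clusterscope compare --a-fasta a.fasta --a-gff a.gff3 \
                     --b-fasta b.fasta --b-gff b.gff3 --out cmp/
clusterscope report --dir cmp/ --out summary.tsv
```

All subcommands accept `--config file` with `key=value` lines (see
`PipelineConfig`); explicit flags win over the config file.  Logs go to
stderr, data to files; reports are stable to 4 decimals.

## Conventions worth knowing

- Identity policies: `all_columns` (gaps/ambiguities count as differences,
  the default), `exclude_gap_columns` (protein-identity convention), and
  `exclude_gap_and_ambiguity` (only genuine substitutions count — the
  "99.99 %" style figure).
- Column classes are mutually exclusive with priority
  gap > ambiguity > match > substitution; two IUPAC codes are *compatible*
  when their base sets intersect (`R` vs `A` is an ambiguity; `R` vs `C` is a
  genuine substitution).
- Default nucleotide gap penalties are stiff (−30/−15): cheap gaps let an
  aligner manufacture >50 % identity between unrelated sequences, which would
  erase the core/flank contrast that boundary detection relies on.
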