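# Deposited cluster sequences

`scripts/acceptance.py` reproduces published comparison numbers from five
deposited echinocandin-cluster sequences.  They are not bundled here; with
network access, fetch them into this directory:

```sh
for acc in JX421684 JX421685 AB720074 KT806042 KP742486; do
  curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=fasta&retmode=text" \
    > ${acc}.fasta
done
```

For the concatenated-ortholog targets (t7/t8) the annotated protein sets are
also needed, as `<ACC>_proteins.fasta` (one record per CDS translation):

```sh
for acc in KT806042 JX421684 JX421685 KP742486; do
  curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=fasta_cds_aa&retmode=text" \
    > ${acc}_proteins.fasta
done
```

The deposited records annotate spliced (multi-exon) CDS, so the records' own
translations are used rather than re-translating single-interval gene models.

Rename the FASTA headers to contain no spaces if your shell keeps the full
NCBI description lines (the pipeline uses the first whitespace-delimited
token as the record id, which is sufficient).

Without these files `scripts/acceptance.py` still runs and exits 0, but
reports an empty target set.
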