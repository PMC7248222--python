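# data/

This directory intentionally ships empty of sequence data.

To enable the reference-genome acceptance tests and targets, download the
PBCV-1 reference (NCBI accession NC_000852, ~0.3 MB) as FASTA, e.g.

```sh
curl -o data/NC_000852.fasta \
  "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=NC_000852&rettype=fasta&retmode=text"
```

and re-run the test suite / `scripts/acceptance.py`. Alternatively set the
`METHYLSTAB_REFERENCE` environment variable to an existing copy.
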