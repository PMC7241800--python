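# Example edit files

`published_revision_subset.tsv` is a **partial** template reproducing the
documented portion of the expert revision of the 1502-sequence flea-beetle
*cox1* library: the three outlier removals (one *Longitarsus atricillus*,
one *L. salviae* and one *L. ochroleucus* sequence that failed taxonomic
validation, with 6.3 %, 17.2 % and 15.2 % divergence from their
conspecifics) and the relabel pattern for the *L. ordinatus* specimens
re-determined as *L. juncicola*.  The full revision comprised at least 69
corrections that were never itemised publicly, so this file cannot be
complete.

The `target` column holds `<record_id>` placeholders: the actual record
identifiers depend on how the library was fetched and must be filled in
against your local copy before running

```bash
barcodeqc revise --in library.fasta --meta metadata.tsv \
    --edits published_revision_subset.tsv --out revised.fasta
```
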