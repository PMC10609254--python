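# Reference data layout

The published-anchor acceptance test (`tests/test_acceptance.py::
TestPublishedAnchors`) checks identity and ANI values against the real
GenBank assemblies. Those assemblies are several megabytes each and are
not bundled; download them and place them here as plain FASTA:

```
data/
  reference_genomes/
    GCF_000621325.1.fasta    # T. lacustris BL (type strain)
    CP133218.fasta           # T. lacustris MK1
    GCF_017901135.1.fasta    # T. litoralis AS (type strain)
    GCF_016772315.1.fasta    # T. subterranea Ku-5 (type strain)
    CP133216.fasta           # T. subterranea DNT52
    GCF_017901155.1.fasta    # Ca. T. anitrata A52
    GCA_017901175.1.fasta    # T. unzii A1 (type strain)
  reference_markers/
    tils.fasta               # one tilS gene copy (any Thiothrix annotation)
    rpob.fasta               # one rpoB gene copy
```

The marker FASTAs seed `locate_marker`, which then extracts each genome's
own gene copy; any annotated *Thiothrix* tilS/rpoB sequence works. The
test fails with the list of missing files until the directory is
populated.
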