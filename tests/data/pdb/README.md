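# Case-study input structures

The acceptance test
`tests/test_acceptance.py::test_case_study_pdz_structure_alignments_are_significant`
aligns two PDZ-domain proteins against the LARG PDZ domain and asserts
highly significant structure alignments (TM-score >= 0.7). It needs three
PDB entries that are not redistributed with this repository; on a machine
with network access, fetch them with:

```bash
cd tests/data/pdb
for id in 2omj 3k82 1tp3; do
    curl -sO https://files.rcsb.org/download/${id}.pdb
done
```

Without these files the test fails with a message pointing here.
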