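# Deposited coordinate files (not shipped)

The reproduction suite and `scripts/reproduce_deposited.py` read the
following files from this directory.  They are experimentally deposited (or
journal-appendix) coordinates, several hundred kilobytes each, and are not
distributed with the package — fetch them when network access is available:

```
curl -o 7ksf.cif https://files.rcsb.org/download/7KSF.cif   # native PFV PR-RT
curl -o 7kse.cif https://files.rcsb.org/download/7KSE.cif   # SeMet CSH mutant
curl -o 2hb4.pdb https://files.rcsb.org/download/2HB4.pdb   # apo HIV-1 PR dimer
# pfv_pr_dimer_model.pdb: the in-silico PFV PR dimer model from the
# publication's supplementary appendix (journal website)
```

All desk-scale tests and `scripts/acceptance.py` are independent of these
files and run entirely on synthetic fixtures.
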