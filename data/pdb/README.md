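# Crystal structures (not redistributed)

The real-structure checks (`analysis/06_real_structures.py` and the final
test in `tests/test_acceptance.py`) operate on two published PRMT1 crystal
structures that are not bundled with this repository. Fetch them from the
RCSB PDB and place them here:

```sh
curl -o data/pdb/1or8.pdb https://files.rcsb.org/download/1OR8.pdb   # rat PRMT1 dimer
curl -o data/pdb/6nt2.pdb https://files.rcsb.org/download/6NT2.pdb   # human PRMT1
```

1OR8 is the rat PRMT1 catalytic core (the head-to-tail dimer used for the
interface decomposition; dimer-arm residues 186–216 with W197/Y202/M206).
6NT2 is the human PRMT1 structure (arm residues 204–234; the rat→human
residue-numbering offset is +18).
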