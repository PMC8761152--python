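# Reference-fold library configuration.
# Paths resolve relative to this file; optional `ranges` carve the TM
# domain ([chain, start, end], author numbering, inclusive).
folds:
  - name: Pgp
    path: refs/pgp_tmd.pdb
    ranges: [[A, 42, 361]]
  - name: ABCG2
    path: refs/abcg2_tmd.pdb
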