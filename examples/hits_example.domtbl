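#                                                               --- full sequence --- --- this domain --- hmm coord ali coord env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
EXAMPLE1             -            200 ABC_membrane         -            100     1e-05   50.0   0.1   1   1     1e-05     1e-05   49.0   0.1     1   100     1   100     1   102 0.90 -
EXAMPLE2             -            200 ABC_membrane         -            100     0.005   50.0   0.1   1   1     0.005     0.005   49.0   0.1    11   100    11   100     9   102 0.90 -
EXAMPLE3             -            300 ABC_tran             -            200    0.0001   50.0   0.1   1   1    0.0001    0.0001   49.0   0.1     1   150     1   150     1   152 0.90 -
#
# Program:         hmmsearch
# Version:         3.4
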