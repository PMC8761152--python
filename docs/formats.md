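# File formats

## Structures

`memqa` reads PDB and mmCIF coordinate files (via gemmi) and writes
minimal C-alpha-only PDB traces. Per-residue model confidence (pLDDT for
predicted models) is read from the B-factor / isotropic-displacement
field of the C-alpha atom; B-factors outside [0, 100] (possible in
experimental entries) yield no confidence value for that residue. Model
1 only; hetero records skipped; first altloc wins; author residue
numbering is preserved verbatim because topology annotations use it.

When writing, a residue without confidence gets B-factor `0.00` by
convention.

## Topology XML

A compact dialect carrying per-residue topology labels as runs, plus the
predictor's reliability score (example:
[`examples/topology_example.xml`](../examples/topology_example.xml)):

```xml
<topologies>
  <protein id="P1" length="40" reliability="95.3">
    <region start="1" end="10" label="I"/>
    <region start="11" end="30" label="M"/>
    <region start="31" end="40" label="O"/>
  </protein>
</topologies>
```

Labels: `I` inside loop, `O` outside loop, `M` membrane-spanning
segment, `L` non-spanning membrane segment (re-entrant loop; excluded
from side assignment, with a warning), `U` unannotated. Bounds are
1-based inclusive. Segment membrane sides come from the nearest flanking
loop label (`I` → side1, `O` → side2). How a given predictor
distinguishes signal peptides from TM helices is outside this schema:
whatever the input labels `M` is treated as membrane-spanning.

Consensus topology predictors publish richer schemas; this dialect keeps
the fields the thickness statistic needs (segment bounds, side labels,
reliability), and the same parser serves generated fixtures and
converted real annotations alike.

## Thickness XML

Experimental hydrophobic thickness records, PDBTM-style: the membrane
element stores the *half*-thickness along the membrane normal; parsed
records carry the full hydrophobic thickness (2x) so they are directly
comparable with the predicted-structure statistic.

```xml
<pdbtm_entries>
  <entry id="1abc"><membrane half_thickness="15.2"/></entry>
</pdbtm_entries>
```

## hmmsearch per-domain tables

Standard HMMER3 `--domtblout` format, parsed with Biopython's SearchIO.
Each domain line yields one hit with the HMM profile length (`qlen`),
the domain's independent E-value (configurable to the full-sequence
E-value), and the HMM-coordinate span used for profile coverage.

## Reference-fold library config

YAML listing fold name, structure path and optional TM-domain carving
ranges; see [`examples/library_example.yaml`](../examples/library_example.yaml).

## Report tables

`memqa qc` and `memqa survey` emit tab-separated tables with a
`#`-prefixed header echoing the tool version and every threshold used,
one row per protein (sorted by id), and trailing `#=` aggregate lines.
Nothing time-dependent enters the output, so repeated runs are
byte-identical.
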