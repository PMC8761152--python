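<?xml version="1.0"?>
<pdbtm_entries>
  <entry id="1abc"><membrane half_thickness="15.2"/></entry>
  <entry id="2def"><membrane half_thickness="14.0"/></entry>
  <entry id="3ghi"><membrane/></entry>
</pdbtm_entries>
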