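<?xml version='1.0' encoding='utf-8'?>
<topologies>
  <protein id="EXAMPLE1" length="65" reliability="95.30">
    <region start="1" end="10" label="I" />
    <region start="11" end="30" label="M" />
    <region start="31" end="35" label="O" />
    <region start="36" end="55" label="M" />
    <region start="56" end="65" label="I" />
  </protein>
  <protein id="EXAMPLE2_SOLUBLE" length="30" reliability="99.00">
    <region start="1" end="30" label="I" />
  </protein>
</topologies>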