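<interface name="discard_dummies" impl_alias="trim_series">
  <currenttask domain="session" desc="Discard pre-steady-state dummy scans" modality="MRI">
    <qsub>
      <memoryBase>0.2</memoryBase>
      <timeBase>1</timeBase>
    </qsub>
    <permanenceofoutput>1</permanenceofoutput>
    <settings>
      <numdummies>3</numdummies>
    </settings>
    <inputstreams>
      <stream>epi</stream>
    </inputstreams>
    <outputstreams>
      <stream>epi</stream>
    </outputstreams>
  </currenttask>
</interface>
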