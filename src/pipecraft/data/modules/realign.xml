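<interface name="realign">
  <currenttask domain="session" desc="Integer-shift motion correction" modality="MRI">
    <qsub>
      <memoryBase>0.5</memoryBase>
      <timeBase>5</timeBase>
    </qsub>
    <permanenceofoutput>2</permanenceofoutput>
    <settings>
      <max_shift>3</max_shift>
    </settings>
    <inputstreams>
      <stream>epi</stream>
    </inputstreams>
    <outputstreams>
      <stream>realignment_parameter</stream>
      <stream>meanepi</stream>
      <stream>epi</stream>
    </outputstreams>
  </currenttask>
</interface>
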