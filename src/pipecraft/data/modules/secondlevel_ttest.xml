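<interface name="secondlevel_ttest">
  <currenttask domain="study" desc="One-sample t-test across subjects per contrast" modality="MRI">
    <qsub>
      <memoryBase>0.5</memoryBase>
      <timeBase>2</timeBase>
    </qsub>
    <permanenceofoutput>4</permanenceofoutput>
    <inputstreams>
      <stream>firstlevel_cons</stream>
    </inputstreams>
    <outputstreams>
      <stream>secondlevel_tmap</stream>
    </outputstreams>
  </currenttask>
</interface>
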