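<interface name="firstlevel_model">
  <currenttask domain="subject" desc="First-level GLM across the subject's sessions" modality="MRI">
    <qsub>
      <memoryBase>1.0</memoryBase>
      <timeBase>5</timeBase>
    </qsub>
    <permanenceofoutput>3</permanenceofoutput>
    <settings>
      <model></model>
      <hrf>boxcar</hrf>
      <tr>2.0</tr>
    </settings>
    <inputstreams>
      <stream>epi</stream>
      <stream>realignment_parameter</stream>
    </inputstreams>
    <outputstreams>
      <stream>firstlevel_betas</stream>
      <stream>firstlevel_cons</stream>
      <stream>firstlevel_tmaps</stream>
    </outputstreams>
  </currenttask>
</interface>
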