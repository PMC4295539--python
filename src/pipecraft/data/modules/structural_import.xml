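<interface name="structural_import">
  <currenttask domain="subject" desc="Import the subject's structural volume" modality="MRI">
    <qsub>
      <memoryBase>0.2</memoryBase>
      <timeBase>1</timeBase>
    </qsub>
    <permanenceofoutput>2</permanenceofoutput>
    <inputstreams/>
    <outputstreams>
      <stream>structural</stream>
    </outputstreams>
  </currenttask>
</interface>
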