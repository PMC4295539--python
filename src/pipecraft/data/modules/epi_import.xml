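<interface name="epi_import">
  <currenttask domain="session" desc="Import one session's 4D EPI series" modality="MRI">
    <qsub>
      <memoryBase>0.2</memoryBase>
      <timeBase>1</timeBase>
    </qsub>
    <permanenceofoutput>1</permanenceofoutput>
    <inputstreams/>
    <outputstreams>
      <stream>epi</stream>
    </outputstreams>
  </currenttask>
</interface>
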