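<interface name="smooth">
  <currenttask domain="session" desc="Gaussian spatial smoothing" modality="MRI">
    <qsub>
      <memoryBase>0.5</memoryBase>
      <timeBase>2</timeBase>
    </qsub>
    <permanenceofoutput>1</permanenceofoutput>
    <settings>
      <FWHM>10</FWHM>
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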