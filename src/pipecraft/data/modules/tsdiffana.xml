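<interface name="tsdiffana">
  <currenttask domain="session" desc="Time-series difference quality control" modality="MRI">
    <qsub>
      <memoryBase>0.3</memoryBase>
      <timeBase>2</timeBase>
    </qsub>
    <permanenceofoutput>2</permanenceofoutput>
    <settings>
      <outlier_factor>4</outlier_factor>
    </settings>
    <inputstreams>
      <stream>epi</stream>
    </inputstreams>
    <outputstreams>
      <stream>qc_timeseries</stream>
    </outputstreams>
  </currenttask>
</interface>
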