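<interface name="checkparameters">
  <currenttask domain="study" desc="Check study description and input series" modality="MRI">
    <qsub>
      <memoryBase>0.1</memoryBase>
      <timeBase>1</timeBase>
    </qsub>
    <permanenceofoutput>0</permanenceofoutput>
    <inputstreams/>
    <outputstreams/>
  </currenttask>
</interface>
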