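<parameters>
  <acq_details>
    <numdummies>3</numdummies>
    <root></root>
  </acq_details>
  <directory_conventions>
    <analysisid>analysis</analysisid>
  </directory_conventions>
  <options>
    <wheretoprocess>localsingle</wheretoprocess>
    <workers>2</workers>
  </options>
</parameters>
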