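<tasklist>
  <initialisation>
    <module><name>checkparameters</name></module>
  </initialisation>
  <main>
    <module><name>epi_import</name></module>
    <module><name>discard_dummies</name></module>
    <module><name>realign</name></module>
    <module><name>tsdiffana</name></module>
    <branch>
      <alternative analysisid_suffix="_s08">
        <module>
          <name>smooth</name>
          <settings><FWHM>8</FWHM></settings>
        </module>
        <module><name>firstlevel_model</name></module>
        <module><name>secondlevel_ttest</name></module>
      </alternative>
      <alternative analysisid_suffix="_s12">
        <module>
          <name>smooth</name>
          <settings><FWHM>12</FWHM></settings>
        </module>
        <module><name>firstlevel_model</name></module>
        <module><name>secondlevel_ttest</name></module>
      </alternative>
    </branch>
  </main>
</tasklist>
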