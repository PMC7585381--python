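<?xml version="1.0" encoding="UTF-8"?>
<dnml version="1.0">
  <spectra>
    <spectrum id="s0" title="example.0" pepmass="500.25" charge="2">
      <peak mz="100.1" intensity="200.0"/>
      <peak mz="250.5" intensity="1500.0"/>
      <peak mz="380.2" intensity="90.5"/>
    </spectrum>
    <spectrum id="s1" title="example.1" pepmass="640.33" charge="2">
      <peak mz="120.2" intensity="80.0"/>
      <peak mz="260.7" intensity="300.0"/>
    </spectrum>
  </spectra>
  <predictions>
    <prediction id="p1" score="0.91" rank="1">
      <source ref="s0"/>
      <sequence>PEPTIDE</sequence>
    </prediction>
    <prediction id="p2" score="0.55" rank="1">
      <source ref="s0"/>
      <source ref="s1"/>
      <sequence>AG(100.00000)K</sequence>
    </prediction>
  </predictions>
</dnml>
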