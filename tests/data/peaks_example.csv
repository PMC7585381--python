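scan,peptide,alc,mz,z
example.0,PEPTIDE,91.5,500.25,2
example.1,S(+79.97)AMPLER,77.2,640.33,2
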