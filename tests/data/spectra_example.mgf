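BEGIN IONS
TITLE=example.0
PEPMASS=500.25
CHARGE=2+
100.1 200.0
250.5 1500.0
380.2 90.5
END IONS
BEGIN IONS
TITLE=example.1
PEPMASS=640.33
CHARGE=2+
120.2 80.0
260.7 300.0
410.9 55.0
522.4 12.0
END IONS
BEGIN IONS
TITLE=example.2
PEPMASS=430.21
110.0 40.0
220.4 75.0
END IONS
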