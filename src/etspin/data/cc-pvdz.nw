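# cc-pVDZ, hydrogen (basis-set-exchange NWChem format)
BASIS "ao basis" PRINT
H    S
     13.0100000              0.0196850
      1.9620000              0.1379770
      0.4446000              0.4781480
      0.1220000              0.5012400
H    S
      0.1220000              1.0000000
H    P
      0.7270000              1.0000000
END
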