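# aug-cc-pVTZ, hydrogen (basis-set-exchange NWChem format)
BASIS "ao basis" PRINT
H    S
     33.8700000              0.0060680
      5.0950000              0.0453080
      1.1590000              0.2028220
H    S
      0.3258000              1.0000000
H    S
      0.1027000              1.0000000
H    S
      0.0252600              1.0000000
H    P
      1.4070000              1.0000000
H    P
      0.3880000              1.0000000
H    P
      0.1020000              1.0000000
H    D
      1.0570000              1.0000000
H    D
      0.2470000              1.0000000
END
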