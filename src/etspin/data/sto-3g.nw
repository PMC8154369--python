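# STO-3G minimal basis, hydrogen (basis-set-exchange NWChem format)
BASIS "ao basis" PRINT
H    S
      3.42525091             0.15432897
      0.62391373             0.53532814
      0.16885540             0.44463454
END
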