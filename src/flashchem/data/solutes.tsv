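# Background (continuum) solutes of the cellular water model.
# Columns: name, concentration (mol/L), depletable (true/false).
# Depletable solutes are integrated as dynamic concentrations in the
# homogeneous stage; non-depletable ones are held at their pool value
# (consumption << pool at <= 30 Gy).
name	concentration	depletable
O2	3.0e-5	true
RH	1.0	false
GSH	6.5e-3	false
AH-	1.0e-3	false
NO	1.0e-6	true
TOH	2.0e-4	false
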