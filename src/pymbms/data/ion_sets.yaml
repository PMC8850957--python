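# Diagnostic ion sets for py-MBMS cell-wall scoring (version 1).
#
# lignin: summation set calibrated against a Klason lignin standard;
#   sublabels mark syringyl (S) and guaiacyl (G) marker ions used for the
#   S/G monomer ratio. Ions without a sublabel count toward lignin content
#   but toward neither monomer.
# c6 / c5: reduced-ion sets for single-point (response-factor) estimation
#   of glucose (C6) and xylose (C5) sugars. m/z 57 and 73 appear in both,
#   as each estimator is applied independently.
version: 1
sets:
  lignin:
    members: [120, 124, 137, 138, 150, 152, 154, 164, 167, 168, 178, 180, 181, 182, 194, 208, 210]
    sublabels:
      124: G
      137: G
      138: G
      150: G
      154: S
      164: G
      167: S
      168: S
      178: G
      182: S
      194: S
      208: S
      210: S
  c6:
    members: [57, 60, 73, 98, 126, 144]
  c5:
    members: [57, 73, 85, 96, 114]
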