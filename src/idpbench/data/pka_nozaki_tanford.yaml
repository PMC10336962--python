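# Intrinsic pKa values of Nozaki & Tanford for titratable side chains and
# chain termini.  Signs: acid groups release a proton to become -1, base
# groups bind a proton to become +1.
sidechains:
  D: {pka: 4.0, kind: acid}
  E: {pka: 4.4, kind: acid}
  H: {pka: 6.3, kind: base}
  C: {pka: 9.5, kind: acid}
  Y: {pka: 9.6, kind: acid}
  K: {pka: 10.4, kind: base}
  R: {pka: 12.0, kind: base}
termini:
  N: {pka: 7.5, kind: base}
  C: {pka: 3.8, kind: acid}
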