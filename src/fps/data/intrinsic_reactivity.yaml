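# Intrinsic hydroxy-radical reactivities (IR) by residue one-letter code,
# on the relative scale used for CheY protection factors (K = 2.2, D = 0.42).
# Only the two published values ship here; extend this file (or pass your own
# table) for other residue types — the package refuses to guess.
K: 2.2
D: 0.42
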