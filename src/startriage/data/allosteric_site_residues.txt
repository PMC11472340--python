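# GCDH allosteric binding-site residues (full-length protein numbering),
# one comma/whitespace-separated list; located at the convergence of the two
# alpha-helical bundle domains, ~12 A from the active site.
Gly107, Pro108, Thr109, Ile110, Ser120, Tyr123, Ser145, Ser146, Met149,
His150, Asn291, Asn292, Tyr295, Leu353, Gly354, Lys357, Ala362, Val367
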