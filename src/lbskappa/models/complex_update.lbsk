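// Updating one of several same-named agents in a homo-multimeric complex:
// the aliases P1/P2/P3 address individual protomers of the triple, and the
// reversible rule flips the conformation site f of the middle one only.
agent P1, P2, P3 = new P{f:(0 1), x:(0 1), y:(0 1), s};

agent c000 = P1{f~0, y!1}-P2{x!1, f~0, y!2, s}-P3{x!2, f~0};
c000 <-> c000<P2{f~1}>
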