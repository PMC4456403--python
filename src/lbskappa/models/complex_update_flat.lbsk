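// Flat directed form of the middle-protomer conformation flip.
agent P1, P2, P3 = new P{f:(0 1), x:(0 1), y:(0 1), s};

P1{f~0, y!1}-P2{x!1, f~0, y!2, s}-P3{x!2, f~0} ->
  P1{f~0, y!1}-P2{x!1, f~1, y!2, s}-P3{x!2, f~0} |
P1{f~0, y!1}-P2{x!1, f~1, y!2, s}-P3{x!2, f~0} ->
  P1{f~0, y!1}-P2{x!1, f~0, y!2, s}-P3{x!2, f~0}
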