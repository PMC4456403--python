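// Generic phosphorylation module: bind, phosphorylate, unbind.
// The kinase k binds the substrate s on the given sites; phosphorylation
// requires the substrate site unphosphorylated; unbinding applies either way.
module phosphorylate(agent k:{m}, s:{n}){
  k{m} + s{n~u} -> k{m!1}-s{n~u!1} |
  k{m!1}-s{n~u!1} -> k{m!1}-s{n~p!1} |
  k{m!1}-s{n!1} -> k{m} + s{n}
};

agent Raf = new {x, y};
agent MEK = new {t, S218, S222};

phosphorylate(Raf:{x}, MEK:{S222})
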