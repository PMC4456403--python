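// A single phosphorylation/dephosphorylation cycle (the first layer of the
// MAPK cascade): Ras activates Raf, PP2A1 deactivates it.
module cycle(agent k:{m}, p:{m}, s:{m}){

  module phosphorylate(agent k:{m}, s:{m}){
    k{m} + s{m~u} -> k{m!1}-s{m~u!1} as c;
    c -> c<s{m~p!e}> |
    k{m!1}-s{m~p!1} -> k{m} + s{m~p}
  };

  module dephosphorylate(agent p:{m}, s:{m}){
    p{m} + s{m~p} -> p{m!1}-s{m~p!1} as c;
    c -> c<s{m~u!e}> |
    p{m!1}-s{m~u!1} -> p{m} + s{m~u}
  };

  phosphorylate(k:{m}, s:{m}) | dephosphorylate(p:{m}, s:{m})
};

agent Ras = new {n:(gtp gdp)};
agent Raf = new {n};
agent PP2A1 = new {n};

cycle(Ras:{n}, PP2A1:{n}, Raf:{n})
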