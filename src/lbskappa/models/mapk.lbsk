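// The MAPK cascade: three layers of phosphorylation cycles.
// The cycle module pairs a phosphorylation sub-module (kinase k) with a
// dephosphorylation sub-module (phosphatase p) acting on substrate s; the
// identity link !e in the catalytic rules leaves the enzyme-substrate bond
// in place while the modification state changes.
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
agent MEK = new {S218, S222, n};
agent ERK = new {T185, Y187};
agent PP2A1 = new {n};
agent PP2A2 = new {n};
agent MKP3 = new {n};

cycle(Ras:{n}, PP2A1:{n}, Raf:{n})|
cycle(Raf{n~p}:{n}, PP2A2:{n}, MEK:{S218})|
cycle(Raf{n~p}:{n}, PP2A2:{n}, MEK:{S222})|
cycle(MEK{S218~p, S222~p, n}:{n}, MKP3:{n}, ERK:{T185})|
cycle(MEK{S218~p, S222~p?, n}:{n}, MKP3:{n}, ERK:{Y187})
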