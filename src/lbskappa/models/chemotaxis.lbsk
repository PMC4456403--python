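// The chemotactic switch ring (conformational-spread subset).
// A protomer P has ring-binding sites x and y, a CheY-binding site s and a
// conformation site f (0 inactive, 1 active).  The flips module holds the
// four conformational-change rules of the middle protomer of a triple, one
// per neighbour-conformation context, each an instance of the single-rule
// flip module; it is instantiated once with the middle protomer free on s
// and once with it bound (wildcard !_), with rate multipliers 1 and 10.
module flips(agent c000: P1{f:(0 1)}-P2{f:(0 1)}-P3{f:(0 1)}; rate k){
  module flip(agent cxxx:P{f:(0 1)}; rate r1; rate r2){
    cxxx<P{f~0}> <->{r1*k}{r2} cxxx<P{f~1}>
  };

  agent c100 = c000<P1{f~1}>;
  agent c001 = c000<P3{f~1}>;
  agent c101 = c000<P1{f~1}><P3{f~1}>;

  flip(c000:P2{f}, 1, 200)|
  flip(c100:P2{f}, 1, 2)|
  flip(c001:P2{f}, 1, 2)|
  flip(c101:P2{f}, 100, 2)
};

agent P1, P2, P3 = new P{f:(0 1), x:(0 1), y:(0 1), s};
agent c000 = P1{f~0, y!1}-P2{x!1, f~0, y!2, s}-P3{x!2, f~0};
agent c000b = c000<P2{s!_}>;

flips(c000:P1{f}-P2{f}-P3{f}, 1)|
flips(c000b:P1{f}-P2{f}-P3{f}, 10)
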