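// Insulin-signalling excerpt: PDK1 phosphorylates PKCz via the standard
// bind-phosphorylate-unbind motif (bpu3), Akt binds AS160 displacing
// Rab10, then phosphorylates and releases it.
//
// The bpu3, pho and unbind module bodies are minimal SYNTHETIC
// reconstructions: the excerpt only shows how the modules are *used*, so
// the bodies below are the evident bind/modify/unbind skeletons needed to
// make it compile; they are not transcriptions.
module bpu3(agent k:{ph, kb}, s:{sm, sb}){
  k{kb} + s{sb} -> k{kb!1}-s{sb!1} |
  k{kb!1}-s{sm~u, sb!1} -> k{kb!1}-s{sm~p, sb!1} |
  k{kb!1}-s{sb!1} -> k{kb} + s{sb}
};

module pho(agent c: A{m}){
  c<A{m~u!e}> -> c<A{m~p!e}>
};

module unbind(agent a:{x}, b:{y}){
  a{x!1}-b{y!1} -> a{x} + b{y}
};

agent Akt = new {PH, T308, S473, as160};
agent AS160 = new {gap, rab};
agent Rab10 = new {g};
agent PDK1 = new {PH, akt, pkc};
agent PKCz = new {T410, pdk1};

bpu3(PDK1{PH}:{PH, pkc}, PKCz:{T410, pdk1})|

Akt{as160, S473~p, T308~p} + AS160{gap~u!1}-Rab10{g~u!1} ->
  Akt{as160!1, S473~p, T308~u}-AS160{gap~u!1} + Rab10{g~u}|

pho(Akt{as160!1}-AS160{gap~u!1}: AS160{gap})|
unbind(Akt:{as160}, AS160:{gap})
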