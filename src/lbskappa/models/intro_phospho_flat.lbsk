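// Hand-inlined flat expansion of the phosphorylation module instantiated
// with Raf (site x) as kinase and MEK (site S222) as substrate.
agent Raf = new {x, y};
agent MEK = new {t, S218, S222};

Raf{x} + MEK{S222~u} -> Raf{x!1}-MEK{S222~u!1} |
Raf{x!1}-MEK{S222~u!1} -> Raf{x!1}-MEK{S222~p!1} |
Raf{x!1}-MEK{S222!1} -> Raf{x} + MEK{S222}
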