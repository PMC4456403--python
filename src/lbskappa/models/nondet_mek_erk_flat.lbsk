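// Flat expansion of the MEK/ERK family binding rule: one concrete rule
// per combination of variants.
agent MEK1 = new MEK{D, S218, S222};
agent MEK2 = new MEK{D, S222, S226};
agent ERK1 = new ERK{CD, T202, Y204};
agent ERK2 = new ERK{CD, T185, Y187};

MEK1{D} + ERK1{CD} -> MEK1{D!1}-ERK1{CD!1} |
MEK1{D} + ERK2{CD} -> MEK1{D!1}-ERK2{CD!1} |
MEK2{D} + ERK1{CD} -> MEK2{D!1}-ERK1{CD!1} |
MEK2{D} + ERK2{CD} -> MEK2{D!1}-ERK2{CD!1}
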