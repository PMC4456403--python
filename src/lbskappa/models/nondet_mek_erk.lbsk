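// Non-deterministic binding between the MEK and ERK protein families.
// M and E each group two variants sharing a common agent name, so the one
// binding rule expands to the four variant combinations.
agent MEK1 = new MEK{D, S218, S222};
agent MEK2 = new MEK{D, S222, S226};
agent ERK1 = new ERK{CD, T202, Y204};
agent ERK2 = new ERK{CD, T185, Y187};

agent M = MEK1 or MEK2;
agent E = ERK1 or ERK2;

M<MEK{D}> + E<ERK{CD}> -> M<MEK{D!1}>-E<ERK{CD!1}>
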