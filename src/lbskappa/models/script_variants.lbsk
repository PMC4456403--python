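// One hundred variants of an agent generated by an embedded script and
// combined into a single non-deterministic agent S; the degradation rule
// after the script expands to one rule per variant.
//
// Original F# script (host language here is Python):
//   let agentNames = seq {for i in 1.. 100 -> "S" + string(i)} in
//   let newDefsLst =
//     Seq.map (fun s -> "agent " + s + " = new{};") agentNames in
//   let newDefsStr = String.concat "\n" newDefsLst in
//   let choiceStr = "agent S = " + (String.concat " or " agentNames) + ";" in
//   newDefsStr + "\n" + choiceStr
script {
    names = ["S" + str(i) for i in range(1, 101)]
    new_defs = "\n".join("agent " + s + " = new{};" for s in names)
    choice = "agent S = " + " or ".join(names) + ";"
    new_defs + "\n" + choice
};

S ->
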