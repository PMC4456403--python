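// Ring initial condition of the chemotactic switch: 34 protomers bound
// x-to-y around a cycle, generated by an embedded script.  Emitted in the
// curly-brace dialect (the F# original emits parenthesis-style agents).
//
// Original F# script:
//   "init " +
//   (seq{ for i in 1.. 34 ->
//       "P(f~0, s, x!" + string(i%34) + ", y!" + string((i+1)%34) + ")" }
//    |> String.concat "-") + " 1;"
agent P = new P{f:(0 1), x:(0 1), y:(0 1), s};

script {
    "init " + "-".join(
        "P{f~0, s, x!" + str(i % 34) + ", y!" + str((i + 1) % 34) + "}"
        for i in range(1, 35)
    ) + " 1;"
}
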