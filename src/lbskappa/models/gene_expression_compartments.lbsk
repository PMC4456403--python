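// Compartmentalised gene expression: transcription in the nucleus,
// transport of mRNA to the cell, translation into MEK, plus the Raf/MEK
// binding rule at the cell level.  Agents without sites model the gene,
// the RNA polymerase and the transcript.
comp cell;
comp nucleus inside cell;

agent Raf = new {x, y};
agent MEK = new {S218, S222};
agent gene = new {};
agent rnap = new {};
agent mRNA = new {};

cell[
  Raf{x~p} + MEK{S222~u} -> Raf{x~p!1}-MEK{S222~u!1} |
  nucleus[
    gene + rnap -> gene + rnap + mRNA
  ] |
  nucleus[mRNA] -> mRNA |
  mRNA -> MEK{S222~u}
]
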