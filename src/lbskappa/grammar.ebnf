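(* Concrete grammar of the .lbsk dialect (ASCII forms; the typeset glyphs
   "→" "↔" "⟨" "⟩" "〈" "〉" "˜" are accepted as aliases of "->" "<->" "<"
   ">" "~").  "//" starts a line comment.  Script block bodies are raw
   host-language text with balanced braces (quotes respected).          *)

program      = [ statement { ( ";" | "|" ) statement } ] ;
statement    = definition | located | invocation | init | rule
             | script | scriptdef | "nil" ;

definition   = agent-def | comp-def | rate-def | module-def ;
agent-def    = "agent" ident { "," ident } "=" agent-expr ;
comp-def     = "comp" ident [ "inside" ident ] ;
rate-def     = "rate" ident "=" rate-expr ;
module-def   = "module" ident "(" [ formals ] ")" "{" program "}" ;
formals      = formal { ( "," | ";" ) formal } ;
formal       = "comp" ident | "rate" ident
             | "agent" ident ":" annotation
             | ident ":" annotation          (* kind persists from the left *)
             | ident ;                        (* comp/rate kind persists *)

located      = ident "[" program "]" ;
invocation   = ident "(" [ actual { "," actual } ] ")" ;
actual       = agent-expr ":" annotation | rate-expr | ident ;
init         = "init" agent-expr integer ;

rule         = side arrow side ;
arrow        = "->"  [ "{" rate-expr "}" ]
             | "<->" [ "{" rate-expr "}" [ "{" rate-expr "}" ] ] ;
side         = [ element { "+" element } ] ;
element      = agent-expr [ "as" ident ] ;

agent-expr   = comp-chain { "or" comp-chain } ;
comp-chain   = postfix { "-" postfix } ;
postfix      = primary { update } ;
update       = "<" { ident "." } ident site-assigns ">" ;
primary      = "new" [ ident ] signature
             | ident "[" agent-expr "]"
             | ident site-assigns             (* atomic-update abbreviation *)
             | ident
             | "(" agent-expr ")" ;

signature    = "{" [ sig-site { "," sig-site } ] "}" ;
sig-site     = ident [ ":" "(" value { value } ")" ] ;
site-assigns = "{" [ site { "," site } ] "}" ;
site         = ident [ "~" ( value | "?" ) ] [ link ] ;
link         = "!" ( integer | "_" | "?" | "e" ) | "?" ;
             (* !k bond label, !_ bound-to-something, ? / !? free-or-bound,
                !e identity (update: leave the bond unchanged); an omitted
                internal state in an update means identity, an omitted link
                means free *)

annotation   = annot-entry { "-" annot-entry } ;
annot-entry  = [ ident ] "{" [ ann-site { "," ann-site } ] "}" ;
ann-site     = ident [ ":" "(" value { value } ")" ] ;

rate-expr    = rate-term { ( "+" | "-" ) rate-term } ;
rate-term    = rate-factor { ( "*" | "/" ) rate-factor } ;
rate-factor  = number | ident | "(" rate-expr ")" ;

script       = "script" "{" raw-host-code "}" ;
scriptdef    = "scriptdef" "{" raw-host-code "}" ;

value        = ident | integer ;
ident        = letter { letter | digit | "_" | "'" } ;
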