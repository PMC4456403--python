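"""Concrete-syntax parser for LBS-kappa.

The dialect accepts both the typeset glyphs used in print (``→``, ``↔``,
``⟨⟩``/``〈〉``, ``˜``) and pure-ASCII equivalents (``->``, ``<->``, ``< >``,
``~``); the pretty-printer emits ASCII.  ``//`` starts a line comment.
The full grammar is published in ``grammar.ebnf`` alongside this module.

Summary of the surface forms::

    agent c = new Shc{PTB:(u p), Y318};     // new agent (sites typed; (u p) default)
    agent P1, P2, P3 = new P{f:(0 1), s};   // aliases of one new agent
    agent c2 = A{x!1}-B{y!1, z~p};          // complex abbreviation
    c2 <-> {0.1}{0.2} c2<B{z~u}>;           // reversible rule with update
    comp nucleus inside cell;               // compartment tree
    cell[ nucleus[mRNA] -> mRNA ]           // located program / transport
    module m(agent k:{x}; rate r){ ... };   // parameterised module
    m(Raf:{x}, 2.5)                         // invocation
    init A{x~u} 100;                        // initial population
    script { ... };  scriptdef { ... };     // embedded host-language code

Site decorations: ``~v`` internal state, ``~?`` explicit wildcard, ``!k``
link label, ``!_`` bound-to-something, ``?`` or ``!?`` free-or-bound, ``!e``
identity link (update leaves the bond unchanged).  An omitted internal state
in an update means identity; an omitted link means free.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .syntax import (
    ActualAgent, ActualExpr, AgentDef, AnnotEntry, Annotation, AsBind,
    Choice, CompDef, Compose, Ident, Init, Invoke, IVal, I_WILD, LAny,
    L_ANY, L_BOUND, L_FREE, L_IDENT, LLabel, Loc, LocP, ModuleDef, NewAgent,
    NIL, Nil, Par, Program, RBin, RConst, RIdent, RateDef, RateExpr, Rule,
    SiteExpr, SiteType, Scoped, Script, ScriptDef, Update,
)

__all__ = ["parse_program", "ParseError", "pretty_print"]

KEYWORDS = {
    "module", "agent", "comp", "rate", "new", "or", "as", "init",
    "inside", "script", "scriptdef", "nil",
}

# glyph normalisation: typeset forms -> ASCII dialect
_GLYPHS = {
    "→": "->",   # →
    "↔": "<->",  # ↔
    "⟨": "<", "〈": "<", "〈": "<",  # ⟨ 〈
    "⟩": ">", "〉": ">", "〉": ">",  # ⟩ 〉
    "˜": "~", "∼": "~",  # ˜ ∼
}

_SYMBOLS = ["<->", "->", "<", ">", "{", "}", "(", ")", "[", "]", ",", ";",
            "|", "+", "-", "*", "/", "!", "~", "?", "_", ":", ".", "="]

_NUM_RE = re.compile(r"\d+(\.\d+)?([eE][+-]?\d+)?")
_NAME_RE = re.compile(r"[A-Za-z][A-Za-z0-9_']*")


class ParseError(Exception):
    def __init__(self, msg: str, line: int = 0, col: int = 0):
        super().__init__(f"{msg} (line {line}, column {col})")
        self.line = line
        self.col = col


@dataclass
class Token:
    kind: str   # symbol itself, or NAME / INT / FLOAT / EOF
    value: str
    line: int
    col: int
    start: int
    end: int


class Lexer:
    def __init__(self, source: str, pos: int = 0):
        self.src = source
        self.pos = pos

    def _line_col(self, pos: int) -> tuple[int, int]:
        line = self.src.count("\n", 0, pos) + 1
        nl = self.src.rfind("\n", 0, pos)
        return line, pos - nl

    def next_token(self) -> Token:
        src, n = self.src, len(self.src)
        while True:
            while self.pos < n and src[self.pos].isspace():
                self.pos += 1
            if self.pos + 1 < n and src[self.pos:self.pos + 2] == "//":
                nl = src.find("\n", self.pos)
                self.pos = n if nl < 0 else nl + 1
                continue
            break
        start = self.pos
        line, col = self._line_col(start)
        if self.pos >= n:
            return Token("EOF", "", line, col, start, start)
        ch = src[self.pos]
        if ch in _GLYPHS:
            self.pos += 1
            sym = _GLYPHS[ch]
            return Token(sym, sym, line, col, start, self.pos)
        for sym in _SYMBOLS:
            if src.startswith(sym, self.pos):
                self.pos += len(sym)
                return Token(sym, sym, line, col, start, self.pos)
        m = _NUM_RE.match(src, self.pos)
        if m:
            self.pos = m.end()
            kind = "FLOAT" if ("." in m.group() or "e" in m.group().lower()) else "INT"
            return Token(kind, m.group(), line, col, start, self.pos)
        m = _NAME_RE.match(src, self.pos)
        if m:
            self.pos = m.end()
            return Token("NAME", m.group(), line, col, start, self.pos)
        raise ParseError(f"unexpected character {ch!r}", line, col)

    def capture_braced(self, open_pos: int) -> tuple[str, int]:
        """Return the raw text between the brace opened at ``open_pos`` and
        its matching close brace, honouring single/double-quoted strings.
        Returns (text, position after the closing brace)."""
        src, n = self.src, len(self.src)
        depth, i = 1, open_pos + 1
        body_start = i
        while i < n:
            ch = src[i]
            if ch in "\"'":
                quote = ch
                i += 1
                while i < n and src[i] != quote:
                    i += 2 if src[i] == "\\" else 1
                if i >= n:
                    raise ParseError("unterminated string in script block",
                                     *self._line_col(open_pos))
                i += 1
                continue
            if ch == "#":  # host-language comment
                nl = src.find("\n", i)
                i = n if nl < 0 else nl + 1
                continue
            if ch == "{":
                depth += 1
            elif ch == "}":
                depth -= 1
                if depth == 0:
                    return src[body_start:i], i + 1
            i += 1
        raise ParseError("unbalanced braces in script block",
                         *self._line_col(open_pos))


_SIDE_END = {";", "|", "]", "EOF", "->", "<->"}


class Parser:
    def __init__(self, source: str):
        self.lexer = Lexer(source)
        self.buf: list[Token] = []

    # token plumbing -----------------------------------------------------

    def peek(self, i: int = 0) -> Token:
        while len(self.buf) <= i:
            self.buf.append(self.lexer.next_token())
        return self.buf[i]

    def next(self) -> Token:
        return self.buf.pop(0) if self.buf else self.lexer.next_token()

    def expect(self, kind: str) -> Token:
        tok = self.peek()
        if tok.kind != kind:
            raise ParseError(f"expected {kind!r}, found {tok.value or tok.kind!r}",
                             tok.line, tok.col)
        return self.next()

    def at_name(self, value: str) -> bool:
        tok = self.peek()
        return tok.kind == "NAME" and tok.value == value

    def expect_ident(self) -> str:
        tok = self.expect("NAME")
        if tok.value in KEYWORDS:
            raise ParseError(f"keyword {tok.value!r} used as identifier",
                             tok.line, tok.col)
        return tok.value

    def save(self):
        return (self.lexer.pos, list(self.buf))

    def restore(self, state) -> None:
        self.lexer.pos, self.buf = state[0], list(state[1])

    # entry point --------------------------------------------------------

    def parse(self) -> Program:
        prog = self.parse_program()
        tok = self.peek()
        if tok.kind != "EOF":
            raise ParseError(f"unexpected {tok.value!r} after program",
                             tok.line, tok.col)
        return prog

    def parse_program(self) -> Program:
        tok = self.peek()
        if tok.kind in ("EOF", "]", "}"):
            return NIL
        kw = tok.value if tok.kind == "NAME" else None
        if kw == "module":
            return self._scoped(self.parse_module_def())
        if kw == "agent":
            return self._scoped(self.parse_agent_def())
        if kw == "comp":
            return self._scoped(self.parse_comp_def())
        if kw == "rate":
            return self._scoped(self.parse_rate_def())
        if kw in ("script", "scriptdef") and self.peek(1).kind == "{":
            return self.parse_script(kw)
        if kw == "init":
            return self._seq(self.parse_init())
        if kw == "nil":
            self.next()
            return self._seq(NIL)
        if tok.kind == "NAME" and kw not in KEYWORDS:
            nxt = self.peek(1).kind
            if nxt == "(":
                return self._seq(self.parse_invoke())
            if nxt == "[" and self._bracket_is_program():
                return self._seq(self.parse_located())
        return self._seq(self.parse_rule())

    def _separator(self) -> bool:
        if self.peek().kind in (";", "|"):
            self.next()
            return True
        return False

    def _scoped(self, defn) -> Program:
        tok = self.peek()
        if tok.kind != ";":
            raise ParseError("expected ';' after definition", tok.line, tok.col)
        self.next()
        return Scoped(defn, self.parse_program())

    def _seq(self, node: Program) -> Program:
        if self._separator():
            rest = self.parse_program()
            if isinstance(rest, Nil):
                return node
            return Par(node, rest)
        tok = self.peek()
        if tok.kind not in ("EOF", "]", "}"):
            raise ParseError(f"expected '|', ';' or end, found {tok.value!r}",
                             tok.line, tok.col)
        return node

    # lookahead: NAME '[' ... ']' — located program or located agent expr?
    def _bracket_is_program(self) -> bool:
        start = self.peek().start
        lx = Lexer(self.lexer.src, start)
        try:
            tok = lx.next_token()          # NAME
            tok = lx.next_token()          # '['
            depth = 1
            while depth > 0:
                tok = lx.next_token()
                if tok.kind == "EOF":
                    return True
                if tok.kind == "NAME" and tok.value in ("script", "scriptdef"):
                    return True
                if tok.kind == "[":
                    depth += 1
                elif tok.kind == "]":
                    depth -= 1
            after = lx.next_token()
        except ParseError:
            return True
        if after.kind in ("->", "<->", "+", "-", "<"):
            return False
        if after.kind == "NAME" and after.value == "as":
            return False
        return True

    # definitions --------------------------------------------------------

    def parse_module_def(self) -> ModuleDef:
        self.next()  # 'module'
        name = self.expect_ident()
        self.expect("(")
        comp_f: list[str] = []
        agent_f: list[tuple[str, Annotation]] = []
        rate_f: list[str] = []
        mode = None
        while self.peek().kind != ")":
            tok = self.peek()
            if tok.kind == "NAME" and tok.value in ("agent", "comp", "rate"):
                mode = tok.value
                self.next()
            if mode is None:
                raise ParseError("formal parameter kind (agent/comp/rate) missing",
                                 tok.line, tok.col)
            if mode == "comp":
                comp_f.append(self.expect_ident())
            elif mode == "rate":
                rate_f.append(self.expect_ident())
            else:
                fid = self.expect_ident()
                self.expect(":")
                agent_f.append((fid, self.parse_annotation()))
            if self.peek().kind in (",", ";"):
                self.next()
        self.expect(")")
        self.expect("{")
        body = self.parse_program()
        self.expect("}")
        return ModuleDef(name, tuple(comp_f), tuple(agent_f), tuple(rate_f), body)

    def parse_agent_def(self) -> AgentDef:
        self.next()  # 'agent'
        idents = [self.expect_ident()]
        while self.peek().kind == ",":
            self.next()
            idents.append(self.expect_ident())
        self.expect("=")
        expr = self.parse_agent_expr()
        return AgentDef(tuple(idents), expr)

    def parse_comp_def(self) -> CompDef:
        self.next()  # 'comp'
        name = self.expect_ident()
        parent = None
        if self.at_name("inside"):
            self.next()
            parent = self.expect_ident()
        return CompDef(name, parent)

    def parse_rate_def(self) -> RateDef:
        self.next()  # 'rate'
        name = self.expect_ident()
        self.expect("=")
        return RateDef(name, self.parse_rate_expr())

    # programs -----------------------------------------------------------

    def parse_script(self, kw: str) -> Program:
        self.next()  # keyword
        tok = self.peek()
        if tok.kind != "{":
            raise ParseError(f"expected '{{' after {kw}", tok.line, tok.col)
        if len(self.buf) > 1:  # must not have pre-lexed the raw body
            raise ParseError("internal lookahead error at script block",
                             tok.line, tok.col)
        code, after = self.lexer.capture_braced(tok.start)
        self.buf.clear()
        self.lexer.pos = after
        self._separator()
        cont = self.parse_program()
        return Script(code, cont) if kw == "script" else ScriptDef(code, cont)

    def parse_located(self) -> LocP:
        comp = self.expect_ident()
        self.expect("[")
        body = self.parse_program()
        self.expect("]")
        return LocP(comp, body)

    def parse_init(self) -> Init:
        self.next()  # 'init'
        expr = self.parse_or_expr()
        tok = self.expect("INT")
        count = int(tok.value)
        if count <= 0:
            raise ParseError("init count must be positive", tok.line, tok.col)
        return Init(expr, count)

    def parse_invoke(self) -> Invoke:
        name = self.expect_ident()
        self.expect("(")
        actuals = []
        while self.peek().kind != ")":
            actuals.append(self.parse_actual())
            if self.peek().kind == ",":
                self.next()
        self.expect(")")
        return Invoke(name, tuple(actuals))

    def parse_actual(self):
        state = self.save()
        try:
            expr = self.parse_or_expr()
            if self.peek().kind == ":":
                self.next()
                return ActualAgent(expr, self.parse_annotation())
            if isinstance(expr, Ident) and self.peek().kind in (",", ")"):
                return ActualExpr(expr.name)
            raise ParseError("not an annotated agent actual", 0, 0)
        except ParseError:
            self.restore(state)
        return ActualExpr(self.parse_rate_expr())

    def parse_rule(self) -> Rule:
        lhs = self.parse_side()
        tok = self.peek()
        if tok.kind not in ("->", "<->"):
            raise ParseError(f"expected '->' or '<->', found {tok.value or 'end'!r}",
                             tok.line, tok.col)
        arrow = self.next().kind
        fwd = RConst(1.0)
        rev = None
        if self.peek().kind == "{":
            self.next()
            fwd = self.parse_rate_expr()
            self.expect("}")
            if arrow == "<->" and self.peek().kind == "{":
                self.next()
                rev = self.parse_rate_expr()
                self.expect("}")
        if arrow == "<->" and rev is None:
            rev = RConst(1.0)
        rhs = self.parse_side()
        if not lhs and not rhs:
            raise ParseError("rule with both sides empty", tok.line, tok.col)
        return Rule(lhs, rhs, fwd, rev)

    def parse_side(self) -> tuple:
        if self.peek().kind in _SIDE_END:
            return ()
        elems = [self.parse_side_element()]
        while self.peek().kind == "+":
            self.next()
            elems.append(self.parse_side_element())
        return tuple(elems)

    def parse_side_element(self):
        expr = self.parse_or_expr()
        if self.at_name("as"):
            self.next()
            return AsBind(expr, self.expect_ident())
        return expr

    # agent expressions --------------------------------------------------

    def parse_agent_expr(self):
        return self.parse_or_expr()

    def parse_or_expr(self):
        left = self.parse_comp_expr()
        while self.at_name("or"):
            self.next()
            left = Choice(left, self.parse_comp_expr())
        return left

    def parse_comp_expr(self):
        left = self.parse_postfix()
        while self.peek().kind == "-":
            self.next()
            left = Compose(left, self.parse_postfix())
        return left

    def parse_postfix(self):
        expr = self.parse_primary()
        while self.peek().kind == "<":
            self.next()
            path: list[str] = []
            name = self.expect_ident()
            while self.peek().kind == ".":
                self.next()
                path.append(name)
                name = self.expect_ident()
            assigns = self.parse_assigns()
            self.expect(">")
            expr = Update(expr, tuple(path), name, assigns)
        return expr

    def parse_primary(self):
        tok = self.peek()
        if tok.kind == "(":
            self.next()
            inner = self.parse_or_expr()
            self.expect(")")
            return inner
        if self.at_name("new"):
            self.next()
            name = None
            if self.peek().kind == "NAME" and self.peek().value not in KEYWORDS:
                name = self.expect_ident()
            sig = self.parse_signature()
            return NewAgent(name, sig)
        name = self.expect_ident()
        nxt = self.peek()
        if nxt.kind == "[":
            self.next()
            body = self.parse_or_expr()
            self.expect("]")
            return Loc(name, body)
        if nxt.kind == "{":
            assigns = self.parse_assigns()
            return Update(Ident(name), (), None, assigns)
        return Ident(name)

    def parse_signature(self) -> tuple:
        self.expect("{")
        sig: list[tuple[str, SiteType]] = []
        seen: set[str] = set()
        while self.peek().kind != "}":
            tok = self.peek()
            site = self.expect_ident()
            if site in seen:
                raise ParseError(f"duplicate site {site!r} in agent signature",
                                 tok.line, tok.col)
            seen.add(site)
            stype = SiteType()
            if self.peek().kind == ":":
                self.next()
                self.expect("(")
                values = []
                while self.peek().kind in ("NAME", "INT"):
                    values.append(self.next().value)
                self.expect(")")
                if not values:
                    raise ParseError("empty site type", tok.line, tok.col)
                stype = SiteType(tuple(values))
            sig.append((site, stype))
            if self.peek().kind == ",":
                self.next()
        self.expect("}")
        return tuple(sig)

    def parse_assigns(self) -> tuple:
        self.expect("{")
        assigns: list[tuple[str, SiteExpr]] = []
        seen: set[str] = set()
        while self.peek().kind != "}":
            tok = self.peek()
            site = self.expect_ident()
            if site in seen:
                raise ParseError(f"duplicate site {site!r} in agent literal",
                                 tok.line, tok.col)
            seen.add(site)
            assigns.append((site, self.parse_site_expr()))
            if self.peek().kind == ",":
                self.next()
        self.expect("}")
        return tuple(assigns)

    def parse_site_expr(self) -> SiteExpr:
        internal = None
        link = None
        if self.peek().kind == "~":
            self.next()
            tok = self.peek()
            if tok.kind == "?":
                self.next()
                internal = I_WILD
            elif tok.kind in ("NAME", "INT"):
                internal = IVal(self.next().value)
            else:
                raise ParseError("expected internal state value after '~'",
                                 tok.line, tok.col)
        tok = self.peek()
        if tok.kind == "!":
            self.next()
            tok = self.peek()
            if tok.kind == "INT":
                link = LLabel(int(self.next().value))
            elif tok.kind == "_":
                self.next()
                link = L_BOUND
            elif tok.kind == "?":
                self.next()
                link = L_ANY
            elif tok.kind == "NAME" and tok.value == "e":
                self.next()
                link = L_IDENT
            else:
                raise ParseError("expected link label, '_', '?' or 'e' after '!'",
                                 tok.line, tok.col)
        elif tok.kind == "?":
            self.next()
            link = L_ANY
        return SiteExpr(internal, link)

    def parse_annotation(self) -> Annotation:
        entries = [self.parse_annot_entry()]
        while self.peek().kind == "-":
            self.next()
            entries.append(self.parse_annot_entry())
        return tuple(entries)

    def parse_annot_entry(self) -> AnnotEntry:
        name = None
        if self.peek().kind == "NAME":
            name = self.expect_ident()
        self.expect("{")
        sites: list[tuple[str, Optional[SiteType]]] = []
        while self.peek().kind != "}":
            site = self.expect_ident()
            stype = None
            if self.peek().kind == ":":
                self.next()
                self.expect("(")
                values = []
                while self.peek().kind in ("NAME", "INT"):
                    values.append(self.next().value)
                self.expect(")")
                stype = SiteType(tuple(values))
            sites.append((site, stype))
            if self.peek().kind == ",":
                self.next()
        self.expect("}")
        return AnnotEntry(name, tuple(sites))

    # rate expressions ---------------------------------------------------

    def parse_rate_expr(self) -> RateExpr:
        left = self.parse_rate_term()
        while self.peek().kind in ("+", "-"):
            op = self.next().kind
            left = RBin(op, left, self.parse_rate_term())
        return left

    def parse_rate_term(self) -> RateExpr:
        left = self.parse_rate_factor()
        while self.peek().kind in ("*", "/"):
            op = self.next().kind
            left = RBin(op, left, self.parse_rate_factor())
        return left

    def parse_rate_factor(self) -> RateExpr:
        tok = self.peek()
        if tok.kind in ("INT", "FLOAT"):
            self.next()
            return RConst(float(tok.value))
        if tok.kind == "NAME" and tok.value not in KEYWORDS:
            self.next()
            return RIdent(tok.value)
        if tok.kind == "(":
            self.next()
            inner = self.parse_rate_expr()
            self.expect(")")
            return inner
        raise ParseError(f"expected rate expression, found {tok.value or tok.kind!r}",
                         tok.line, tok.col)


def parse_program(source: str) -> Program:
    """Parse a complete LBS-kappa model; the empty input is the nil program."""
    return Parser(source).parse()


# ---------------------------------------------------------------------------
# Pretty-printer (ASCII dialect); parse(pretty_print(ast)) round-trips.


def _pp_num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(x)


def pp_rate(e: RateExpr, prec: int = 0) -> str:
    if isinstance(e, RConst):
        return _pp_num(e.value)
    if isinstance(e, RIdent):
        return e.name
    inner_prec = 1 if e.op in ("*", "/") else 0
    s = f"{pp_rate(e.left, inner_prec)} {e.op} {pp_rate(e.right, inner_prec + 1)}"
    return f"({s})" if inner_prec < prec else s


def pp_site(name: str, e: SiteExpr) -> str:
    out = name
    if isinstance(e.internal, IVal):
        out += f"~{e.internal.value}"
    elif e.internal == I_WILD:
        out += "~?"
    link = e.link
    if isinstance(link, LLabel):
        out += f"!{link.k}"
    elif link is None:
        pass
    elif isinstance(link, LAny):
        out += "!?"
    elif link == L_BOUND:
        out += "!_"
    elif link == L_IDENT:
        out += "!e"
    return out


def pp_sig(sig) -> str:
    parts = []
    for site, stype in sig:
        if stype == SiteType():
            parts.append(site)
        else:
            parts.append(f"{site}:({' '.join(stype.values)})")
    return "{" + ", ".join(parts) + "}"


def pp_expr(e, prec: int = 0) -> str:
    # precedence: 0 or, 1 compose, 2 postfix/primary
    if isinstance(e, Choice):
        s = f"{pp_expr(e.left, 0)} or {pp_expr(e.right, 1)}"
        return f"({s})" if prec > 0 else s
    if isinstance(e, Compose):
        s = f"{pp_expr(e.left, 1)}-{pp_expr(e.right, 2)}"
        return f"({s})" if prec > 1 else s
    if isinstance(e, Update):
        assigns = "{" + ", ".join(pp_site(n, se) for n, se in e.assigns) + "}"
        if e.target is None and isinstance(e.base, Ident):
            return f"{e.base.name}{assigns}"
        path = "".join(f"{c}." for c in e.path)
        return f"{pp_expr(e.base, 2)}<{path}{e.target}{assigns}>"
    if isinstance(e, NewAgent):
        name = f" {e.name}" if e.name else ""
        return f"new{name}{pp_sig(e.sig)}"
    if isinstance(e, Loc):
        return f"{e.comp}[{pp_expr(e.body, 0)}]"
    if isinstance(e, Ident):
        return e.name
    if isinstance(e, AsBind):
        return f"{pp_expr(e.body, 0)} as {e.ident}"
    raise TypeError(f"cannot print {e!r}")


def pp_annotation(a: Annotation) -> str:
    parts = []
    for entry in a:
        sites = []
        for site, stype in entry.sites:
            if stype is None:
                sites.append(site)
            else:
                sites.append(f"{site}:({' '.join(stype.values)})")
        parts.append(f"{entry.name or ''}{{{', '.join(sites)}}}")
    return "-".join(parts)


def _pp_defn(d) -> str:
    if isinstance(d, AgentDef):
        return f"agent {', '.join(d.idents)} = {pp_expr(d.expr)};"
    if isinstance(d, CompDef):
        inside = f" inside {d.parent}" if d.parent else ""
        return f"comp {d.name}{inside};"
    if isinstance(d, RateDef):
        return f"rate {d.name} = {pp_rate(d.expr)};"
    if isinstance(d, ModuleDef):
        formals = []
        for c in d.comp_formals:
            formals.append(f"comp {c}")
        for fid, annot in d.agent_formals:
            formals.append(f"agent {fid}:{pp_annotation(annot)}")
        for r in d.rate_formals:
            formals.append(f"rate {r}")
        body = pretty_print(d.body)
        return f"module {d.name}({'; '.join(formals)}){{\n{body}\n}};"
    raise TypeError(f"cannot print {d!r}")


def _pp_actual(a) -> str:
    if isinstance(a, ActualAgent):
        return f"{pp_expr(a.expr)}:{pp_annotation(a.annot)}"
    if isinstance(a.expr, str):
        return a.expr
    return pp_rate(a.expr)


def pretty_print(p: Program) -> str:
    """Serialise a program AST back to concrete (ASCII) syntax."""
    if isinstance(p, Nil):
        return "nil"
    if isinstance(p, Par):
        return f"{pretty_print(p.left)} |\n{pretty_print(p.right)}"
    if isinstance(p, Scoped):
        return f"{_pp_defn(p.defn)}\n{pretty_print(p.body)}"
    if isinstance(p, LocP):
        return f"{p.comp}[\n{pretty_print(p.body)}\n]"
    if isinstance(p, Rule):
        lhs = " + ".join(pp_expr(e) for e in p.lhs)
        rhs = " + ".join(pp_expr(e) for e in p.rhs)
        if p.rev is not None:
            arrow = f"<-> {{{pp_rate(p.fwd)}}}{{{pp_rate(p.rev)}}}"
        elif p.fwd == RConst(1.0):
            arrow = "->"
        else:
            arrow = f"-> {{{pp_rate(p.fwd)}}}"
        return f"{lhs} {arrow} {rhs}".strip()
    if isinstance(p, Invoke):
        return f"{p.module}({', '.join(_pp_actual(a) for a in p.actuals)})"
    if isinstance(p, Init):
        return f"init {pp_expr(p.expr)} {p.count}"
    if isinstance(p, Script):
        return f"script {{{p.code}}};\n{pretty_print(p.cont)}"
    if isinstance(p, ScriptDef):
        return f"scriptdef {{{p.code}}};\n{pretty_print(p.cont)}"
    raise TypeError(f"cannot print {p!r}")
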