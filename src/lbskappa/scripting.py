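"""Embedded host-language scripts.

``script { ... }`` blocks contain host-language (Python) code whose value
is a string: an LBS-kappa program fragment with an implicit *hole* at the
end.  The fragment is parsed, the continuation of the block is spliced into
the hole, and compilation recurses.  ``scriptdef { ... }`` blocks contain
definitions only; they are concatenated, in program order, into a script
environment that is prepended to every subsequent script evaluation.

Scripts run in a restricted namespace: a curated set of pure builtins
(string/sequence helpers), no filesystem, network or import access.  The
block's value is the value of its final expression statement.
"""

from __future__ import annotations

import ast as py_ast
import textwrap
from dataclasses import dataclass

from .syntax import (
    Init, Invoke, LocP, Nil, Par, Program, Rule, Scoped, Script, ScriptDef,
)


class ScriptError(Exception):
    pass


_SAFE_BUILTINS = {
    name: __builtins__[name] if isinstance(__builtins__, dict)
    else getattr(__builtins__, name)
    for name in (
        "abs", "all", "any", "bool", "dict", "divmod", "enumerate", "filter",
        "float", "format", "frozenset", "int", "len", "list", "map", "max",
        "min", "range", "repr", "reversed", "round", "set", "sorted", "str",
        "sum", "tuple", "zip",
    )
}


@dataclass(frozen=True)
class ScriptEnvironment:
    """Accumulated script definitions: a string, appended in scope order."""

    defs: str = ""

    def collect(self, code: str) -> "ScriptEnvironment":
        """Append a ``scriptdef`` body after checking it is definition-grade
        (no bare expression statements at top level)."""
        code = textwrap.dedent(code)
        try:
            tree = py_ast.parse(code)
        except SyntaxError as exc:
            raise ScriptError(f"scriptdef block does not parse: {exc}") from exc
        for node in tree.body:
            if isinstance(node, py_ast.Expr):
                raise ScriptError(
                    "scriptdef blocks may only contain definitions, found a "
                    f"bare expression at line {node.lineno}")
            if isinstance(node, (py_ast.Import, py_ast.ImportFrom)):
                raise ScriptError("imports are not allowed in script blocks")
        return ScriptEnvironment(self.defs + code + "\n")


def run_script(code: str, env: ScriptEnvironment) -> str:
    """Evaluate a script block under the accumulated definitions; the value
    of the final expression must be a string (the program fragment)."""
    source = env.defs + textwrap.dedent(code)
    try:
        tree = py_ast.parse(source)
    except SyntaxError as exc:
        raise ScriptError(f"script block does not parse: {exc}") from exc
    if not tree.body or not isinstance(tree.body[-1], py_ast.Expr):
        raise ScriptError("script block must end in a string-valued expression")
    for node in py_ast.walk(tree):
        if isinstance(node, (py_ast.Import, py_ast.ImportFrom)):
            raise ScriptError("imports are not allowed in script blocks")
    *stmts, final = tree.body
    namespace: dict = {"__builtins__": _SAFE_BUILTINS}
    try:
        exec(compile(py_ast.Module(stmts, []), "<script>", "exec"), namespace)
        value = eval(compile(py_ast.Expression(final.value), "<script>", "eval"),
                     namespace)
    except ScriptError:
        raise
    except Exception as exc:
        raise ScriptError(f"script evaluation failed: {exc}") from exc
    if not isinstance(value, str):
        raise ScriptError(
            f"script value must be a string, got {type(value).__name__}")
    return value


def splice(generated: Program, continuation: Program) -> Program:
    """Insert the continuation into the hole at the end of a
    script-generated program."""
    if isinstance(generated, Nil):
        return continuation
    if isinstance(generated, Scoped):
        return Scoped(generated.defn, splice(generated.body, continuation))
    if isinstance(generated, Par):
        return Par(generated.left, splice(generated.right, continuation))
    if isinstance(generated, Script):
        return Script(generated.code, splice(generated.cont, continuation))
    if isinstance(generated, ScriptDef):
        return ScriptDef(generated.code, splice(generated.cont, continuation))
    if isinstance(generated, (Rule, Invoke, Init, LocP)):
        if isinstance(continuation, Nil):
            return generated
        return Par(generated, continuation)
    raise ScriptError(f"cannot splice into {generated!r}")
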