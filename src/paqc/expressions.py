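"""Boolean expressions over sign documentation.

Guideline assessment rules ("pallor in the presence of grunting or
indrawing", "capillary refill or AVPU ... and pulse") are encoded in the
codebook file as nested any/all expressions over canonical sign names and
evaluated against the *documentation* state of a record: a leaf is true
iff the sign is documented (present, absent or with a value).

The synthetic generator uses the same expressions in reverse, choosing
sign sets that make an expression true (``satisfy``) or false
(``violate``) subject to signs that must stay documented/undocumented.
"""

from __future__ import annotations

from typing import Iterable, Union

Expr = Union[str, dict]  # "sign" | {"any": [Expr, ...]} | {"all": [Expr, ...]}


def validate_expr(expr: Expr, vocabulary: Iterable[str]) -> None:
    vocab = set(vocabulary)
    if isinstance(expr, str):
        if expr not in vocab:
            raise ValueError(f"unknown sign {expr!r} in expression")
        return
    if isinstance(expr, dict) and len(expr) == 1:
        op, args = next(iter(expr.items()))
        if op in ("any", "all") and isinstance(args, list) and args:
            for a in args:
                validate_expr(a, vocab)
            return
    raise ValueError(f"malformed expression {expr!r}")


def expr_signs(expr: Expr) -> set[str]:
    """All sign names appearing anywhere in the expression."""
    if isinstance(expr, str):
        return {expr}
    (args,) = expr.values()
    out: set[str] = set()
    for a in args:
        out |= expr_signs(a)
    return out


def evaluate(expr: Expr, documented: set[str]) -> bool:
    if isinstance(expr, str):
        return expr in documented
    op, args = next(iter(expr.items()))
    if op == "any":
        return any(evaluate(a, documented) for a in args)
    return all(evaluate(a, documented) for a in args)


def satisfying_set(expr: Expr, avoid: frozenset[str] = frozenset()) -> set[str] | None:
    """A small set of signs whose documentation makes ``expr`` true.

    Prefers choices disjoint from ``avoid`` (signs some other rule needs
    undocumented); returns None only when every realisation intersects
    ``avoid``.
    """
    if isinstance(expr, str):
        return None if expr in avoid else {expr}
    op, args = next(iter(expr.items()))
    if op == "all":
        out: set[str] = set()
        for a in args:
            s = satisfying_set(a, avoid)
            if s is None:
                return None
            out |= s
        return out
    # any: first satisfiable branch, preferring the smallest clean one
    best: set[str] | None = None
    for a in args:
        s = satisfying_set(a, avoid)
        if s is not None and (best is None or len(s) < len(best)):
            best = s
    return best


def violating_set(expr: Expr, keep: frozenset[str] = frozenset()) -> set[str] | None:
    """A set of signs that must stay undocumented to make ``expr`` false.

    ``keep`` are signs already pledged as documented; a violation needing
    any of them is infeasible. Returns None when no feasible violation
    exists (the expression will evaluate true regardless).
    """
    if isinstance(expr, str):
        return None if expr in keep else {expr}
    op, args = next(iter(expr.items()))
    if op == "any":
        out: set[str] = set()
        for a in args:
            s = violating_set(a, keep)
            if s is None:
                return None
            out |= s
        return out
    # all: falsifying one conjunct suffices; prefer the smallest feasible one
    best: set[str] | None = None
    for a in args:
        s = violating_set(a, keep)
        if s is not None and (best is None or len(s) < len(best)):
            best = s
    return best
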