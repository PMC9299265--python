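"""The symbol vocabulary used to build kernel expressions.

Seven symbols exist: three scalar operators (``Plus_s``, ``Minus_s``,
``Multi_s``), two vector operators (``Plus_v``, ``Minus_v``) and two
operands (``x``, ``y``) standing for the pair of input feature vectors.

Each symbol carries an ``arity`` value as published metadata (scalar
operators and operands: 1; vector operators: 2).  Tree decoding does not
consult it: every internal node of a decoded chromosome has exactly two
children, read from its ``left.right`` folding index, which is the
structure the reference genotypes exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Symbol",
    "SYMBOLS",
    "OPERATORS",
    "SCALAR_OPERATORS",
    "VECTOR_OPERATORS",
    "OPERANDS",
    "TERMINAL_SYMBOLS",
    "get_symbol",
]


@dataclass(frozen=True)
class Symbol:
    """One entry of the kernel-building vocabulary.

    Attributes
    ----------
    name : str
        Canonical printed name, e.g. ``"Plus_s"``.
    category : str
        ``"operator"`` or ``"operand"``.
    value_kind : str
        ``"scalar-op"``, ``"vector-op"`` or ``"operand"``.
    arity : int
        Published arity metadata (not used by the decoder).
    """

    name: str
    category: str
    value_kind: str
    arity: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name

    @property
    def is_operator(self) -> bool:
        return self.category == "operator"

    @property
    def is_operand(self) -> bool:
        return self.category == "operand"

    @property
    def is_scalar_op(self) -> bool:
        return self.value_kind == "scalar-op"

    @property
    def is_vector_op(self) -> bool:
        return self.value_kind == "vector-op"

    @property
    def may_be_terminal(self) -> bool:
        """Operands always; vector operators may act terminally (direct
        application to the input pair); scalar operators never."""
        return self.is_operand or self.is_vector_op


SYMBOLS: dict[str, Symbol] = {
    s.name: s
    for s in (
        Symbol("Plus_s", "operator", "scalar-op", 1),
        Symbol("Minus_s", "operator", "scalar-op", 1),
        Symbol("Multi_s", "operator", "scalar-op", 1),
        Symbol("Plus_v", "operator", "vector-op", 2),
        Symbol("Minus_v", "operator", "vector-op", 2),
        Symbol("x", "operand", "operand", 1),
        Symbol("y", "operand", "operand", 1),
    )
}

SCALAR_OPERATORS: tuple[str, ...] = ("Plus_s", "Minus_s", "Multi_s")
VECTOR_OPERATORS: tuple[str, ...] = ("Plus_v", "Minus_v")
OPERATORS: tuple[str, ...] = SCALAR_OPERATORS + VECTOR_OPERATORS
OPERANDS: tuple[str, ...] = ("x", "y")
#: Symbols legal in a leaf position.
TERMINAL_SYMBOLS: tuple[str, ...] = OPERANDS + VECTOR_OPERATORS


def get_symbol(name: str) -> Symbol:
    """Look up a symbol by its printed name; raise ``KeyError`` if unknown."""
    try:
        return SYMBOLS[name]
    except KeyError:
        raise KeyError(f"unknown symbol {name!r}; valid: {sorted(SYMBOLS)}") from None
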