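"""Genotype representation for Genetic Folding.

A chromosome is an ordered list of genes; each gene holds a symbol and a
*folding index* ``left.right``.  Gene ``i`` with fold ``0.i`` (a
self-reference) acts as a terminal; any other fold makes it an internal
node whose two children sit at positions ``left`` and ``right``, both
strictly greater than ``i``.  Forward references guarantee acyclicity, and
a valid chromosome's folds form a binary tree spanning *all* genes with
gene 0 as the root (hence valid chromosomes always have an odd gene
count).  The head of the chromosome is an operators-only prefix; the tail
closes every dangling child slot with operands or terminal-acting vector
operators.

:func:`decode` turns (symbols, folds) into a :class:`~genefold.kernel.KernelExpression`;
:func:`encode` emits genes back in breadth-first order so that
``decode(encode(t)) == t``.
"""

from __future__ import annotations

import json
import re
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    GenerationError,
    InvalidTerminalError,
    MalformedChromosomeError,
    SpanningTreeError,
)
from .kernel import KernelExpression
from .symbols import OPERANDS, VECTOR_OPERATORS, Symbol, get_symbol

__all__ = [
    "FoldIndex",
    "Gene",
    "Chromosome",
    "ValidationReport",
    "decode",
    "encode",
    "validate",
    "random_chromosome",
    "rebuild_from_symbols",
    "complexity",
]

_FOLD_RE = re.compile(r"^(\d+)\.(\d+)$")


@dataclass(frozen=True)
class FoldIndex:
    """A ``left.right`` child-position pair; ``0.i`` at position i marks a terminal."""

    left: int
    right: int

    def __post_init__(self) -> None:
        if self.left < 0 or self.right < 0:
            raise MalformedChromosomeError(f"negative fold index {self}")

    def __str__(self) -> str:
        return f"{self.left}.{self.right}"

    @staticmethod
    def parse(text: str) -> "FoldIndex":
        m = _FOLD_RE.match(text.strip())
        if not m:
            raise MalformedChromosomeError(f"fold index {text!r} does not parse as 'left.right'")
        return FoldIndex(int(m.group(1)), int(m.group(2)))

    def is_terminal_at(self, position: int) -> bool:
        return self.left == 0 and self.right == position


@dataclass(frozen=True)
class Gene:
    """One chromosome position: symbol plus folding index."""

    position: int
    symbol: Symbol
    fold: FoldIndex

    @property
    def is_terminal(self) -> bool:
        return self.fold.is_terminal_at(self.position)


@dataclass
class Chromosome:
    """Ordered gene list; the genotype of one kernel function."""

    genes: list[Gene]
    head_length: int | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def symbols(self) -> list[str]:
        return [g.symbol.name for g in self.genes]

    def folds(self) -> list[str]:
        return [str(g.fold) for g in self.genes]

    def key(self) -> str:
        """Canonical serialization, usable as a cache key."""
        return ";".join(f"{s}:{f}" for s, f in zip(self.symbols(), self.folds()))

    # -- plain-text bracketed dialect -------------------------------------
    def to_bracketed(self) -> str:
        """Two bracketed, quoted lists (symbols line, folds line)."""
        return _format_bracketed(self.symbols()) + "\n" + _format_bracketed(self.folds())

    @staticmethod
    def from_bracketed(text: str) -> "Chromosome":
        """Parse the two-bracketed-list dialect (symbols first, folds second)."""
        lists = re.findall(r"\[[^\]]*\]", text)
        if len(lists) < 2:
            raise MalformedChromosomeError(
                "expected two bracketed lists (symbols, folds), found "
                f"{len(lists)}"
            )
        return Chromosome.from_lists(_parse_bracketed(lists[0]), _parse_bracketed(lists[1]))

    @staticmethod
    def from_lists(symbols: list[str], folds: list[str], head_length: int | None = None) -> "Chromosome":
        if len(symbols) != len(folds):
            raise MalformedChromosomeError(
                f"{len(symbols)} symbols but {len(folds)} folding indices"
            )
        if not symbols:
            raise MalformedChromosomeError("empty chromosome")
        genes = [
            Gene(i, get_symbol(s), FoldIndex.parse(f))
            for i, (s, f) in enumerate(zip(symbols, folds))
        ]
        return Chromosome(genes, head_length)

    # -- JSON record ------------------------------------------------------
    def to_json(self, **extra) -> str:
        rec = {"symbols": self.symbols(), "folds": self.folds()}
        rec.update(extra)
        return json.dumps(rec, indent=2)

    @staticmethod
    def from_json(text: str) -> "Chromosome":
        rec = json.loads(text)
        return Chromosome.from_lists(list(rec["symbols"]), list(rec["folds"]))


def _format_bracketed(items: list[str]) -> str:
    return "[" + ", ".join(f"'{it}'" for it in items) + "]"


def _parse_bracketed(text: str) -> list[str]:
    inner = text.strip()
    if not (inner.startswith("[") and inner.endswith("]")):
        raise MalformedChromosomeError(f"not a bracketed list: {text!r}")
    inner = inner[1:-1].strip()
    if not inner:
        return []
    items = []
    for raw in inner.split(","):
        it = raw.strip().strip("'\"‘’")
        if it:
            items.append(it)
    return items


# ---------------------------------------------------------------------------
# decode / encode
# ---------------------------------------------------------------------------

def decode(symbols: list[str], folds: list[str]) -> KernelExpression:
    """Decode a genotype into its kernel parse tree.

    Gene ``i`` with fold ``a.b`` becomes an internal node with children
    decoded at positions ``a`` and ``b``; ``0.i`` makes it a leaf.  Raises
    on out-of-range or backward references, scalar operators in terminal
    position, and folds that do not span all genes exactly once.
    """
    c = Chromosome.from_lists(list(symbols), list(folds))
    _check_structure(c)
    n = len(c.genes)
    nodes: list[KernelExpression | None] = [None] * n
    for i in range(n - 1, -1, -1):
        g = c.genes[i]
        if g.is_terminal:
            nodes[i] = KernelExpression(g.symbol)
        else:
            left = nodes[g.fold.left]
            right = nodes[g.fold.right]
            assert left is not None and right is not None  # forward refs
            nodes[i] = KernelExpression(g.symbol, (left, right))
    assert nodes[0] is not None
    return nodes[0]


def _check_structure(c: Chromosome) -> None:
    """Raise the first structural violation found in ``c``."""
    n = len(c.genes)
    ref_count = [0] * n
    for g in c.genes:
        if g.is_terminal:
            if not g.symbol.may_be_terminal:
                raise InvalidTerminalError(
                    f"scalar operator {g.symbol.name!r} in terminal position {g.position}"
                )
            continue
        a, b = g.fold.left, g.fold.right
        if a >= n or b >= n:
            raise MalformedChromosomeError(
                f"gene {g.position}: child index {max(a, b)} out of range for {n} genes"
            )
        if a <= g.position or b <= g.position:
            raise MalformedChromosomeError(
                f"gene {g.position}: backward reference in fold {g.fold} "
                "(children must sit at later positions)"
            )
        if not g.symbol.is_operator:
            raise MalformedChromosomeError(
                f"gene {g.position}: operand {g.symbol.name!r} cannot be an internal node"
            )
        ref_count[a] += 1
        ref_count[b] += 1
    if ref_count[0] != 0:
        raise SpanningTreeError("root gene 0 is referenced as a child")
    for i in range(1, n):
        if ref_count[i] == 0:
            raise SpanningTreeError(f"gene {i} is unreachable (never referenced)")
        if ref_count[i] > 1:
            raise SpanningTreeError(f"gene {i} is referenced by {ref_count[i]} parents")
    # counts + forward references imply reachability, but verify explicitly
    # so that invalid input can never slip through as an infinite structure
    seen = set()
    queue = deque([0])
    while queue:
        i = queue.popleft()
        if i in seen:
            raise SpanningTreeError(f"cycle detected through gene {i}")
        seen.add(i)
        g = c.genes[i]
        if not g.is_terminal:
            queue.append(g.fold.left)
            queue.append(g.fold.right)
    if len(seen) != n:
        raise SpanningTreeError(
            f"folds span only {len(seen)} of {n} genes"
        )


def encode(expr: KernelExpression) -> tuple[list[str], list[str]]:
    """Emit (symbols, folds) in breadth-first order from the root.

    Inverse of :func:`decode`: terminal leaves emit ``0.i`` self-references,
    internal nodes reference the positions their children are assigned.
    """
    order: list[KernelExpression] = []
    queue = deque([expr])
    while queue:
        node = queue.popleft()
        order.append(node)
        queue.extend(node.children)
    symbols, folds = [], []
    next_child = 1
    for i, node in enumerate(order):
        symbols.append(node.symbol.name)
        if node.is_leaf:
            folds.append(f"0.{i}")
        else:
            folds.append(f"{next_child}.{next_child + 1}")
            next_child += 2
    assert next_child == len(order) or (len(order) == 1 and next_child == 1)
    return symbols, folds


# ---------------------------------------------------------------------------
# validation (diagnostic, never raises)
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def validate(c: Chromosome) -> ValidationReport:
    """Diagnostic validity check: pass/fail plus the violated invariants.

    Checks fold range, forward references, the spanning-tree property,
    terminal legality (no scalar-operator leaves, no internal operands)
    and, when ``head_length`` is set, the operators-only head composition.
    Never raises.
    """
    violations: list[str] = []
    n = len(c.genes)
    if n == 0:
        return ValidationReport(False, ["empty chromosome"])
    try:
        _check_structure(c)
    except (MalformedChromosomeError, InvalidTerminalError, SpanningTreeError) as exc:
        violations.append(str(exc))
    if c.head_length is not None:
        head = c.genes[: c.head_length]
        for g in head:
            if not g.symbol.is_operator:
                violations.append(
                    f"gene {g.position}: operand {g.symbol.name!r} inside the "
                    f"operators-only head (head_length={c.head_length})"
                )
    for i, g in enumerate(c.genes):
        if g.position != i:
            violations.append(f"gene at slot {i} carries position {g.position}")
    return ValidationReport(not violations, violations)


# ---------------------------------------------------------------------------
# generation and repair
# ---------------------------------------------------------------------------

def rebuild_from_symbols(
    symbols: list[str],
    rng: np.random.Generator,
    operand_pool: tuple[str, ...] = OPERANDS,
) -> Chromosome:
    """Close a bare symbol string into a valid chromosome (repair step).

    Starting from the root, child slots are allocated breadth-first:
    an operator becomes internal whenever two unallocated positions remain,
    otherwise it acts terminally.  A scalar operator forced into a terminal
    slot is replaced by a random operand (scalar operators have no direct
    form on the input pair).  Positions the closure never reaches are
    dropped, so the result is always a valid spanning chromosome.
    """
    L = len(symbols)
    if L == 0:
        raise GenerationError("cannot rebuild an empty symbol string")
    syms = list(symbols)
    folds: dict[int, FoldIndex] = {}
    queue = deque([0])
    next_free = 1
    while queue:
        i = queue.popleft()
        sym = get_symbol(syms[i])
        if sym.is_operator and next_free + 1 < L:
            folds[i] = FoldIndex(next_free, next_free + 1)
            queue.append(next_free)
            queue.append(next_free + 1)
            next_free += 2
        else:
            if not sym.may_be_terminal:
                syms[i] = str(rng.choice(list(operand_pool)))
            folds[i] = FoldIndex(0, i)
    used = next_free
    genes = [Gene(i, get_symbol(syms[i]), folds[i]) for i in range(used)]
    return Chromosome(genes)


def random_chromosome(config, rng: np.random.Generator) -> Chromosome:
    """Draw a random valid chromosome under ``config``.

    The head (an operators-only prefix) is drawn from the operator pool with
    a length sampled up to the configured head budget; the tail then grows
    automatically until every dangling child slot is closed with an operand
    or a terminal-acting vector operator, so total size is ``2*h + 1`` and
    never exceeds the gene cap.
    """
    head_budget = int(config.head_length)
    cap = int(config.gene_cap)
    if head_budget < 1:
        raise GenerationError(f"head_length must be >= 1, got {head_budget}")
    if cap < 3:
        raise GenerationError(f"gene_cap={cap} cannot close a single operator's child slots")
    operator_pool = tuple(config.operator_pool)
    operand_pool = tuple(config.operand_pool)
    if not operator_pool or not operand_pool:
        raise GenerationError("operator and operand pools must be non-empty")
    h_max = min(head_budget, (cap - 1) // 2)
    h = int(rng.integers(1, h_max + 1))
    terminal_pool = tuple(operand_pool) + tuple(
        s for s in operator_pool if s in VECTOR_OPERATORS
    )
    genes: list[Gene] = []
    queue = deque([0])
    next_free = 1
    while queue:
        i = queue.popleft()
        if i < h:
            name = str(rng.choice(list(operator_pool)))
            genes.append(Gene(i, get_symbol(name), FoldIndex(next_free, next_free + 1)))
            queue.append(next_free)
            queue.append(next_free + 1)
            next_free += 2
        else:
            name = str(rng.choice(list(terminal_pool)))
            genes.append(Gene(i, get_symbol(name), FoldIndex(0, i)))
    genes.sort(key=lambda g: g.position)
    return Chromosome(genes, head_length=h)


def complexity(c: Chromosome) -> int:
    """Gene count — the x-axis of accuracy-versus-complexity traces."""
    return len(c.genes)
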