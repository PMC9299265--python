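"""Kernel expression semantics: evaluating decoded trees and Gram matrices.

A :class:`KernelExpression` is the phenotype of a chromosome: a binary tree
whose leaves are the input vectors ``x`` and ``y`` (or a vector operator
applied directly to the pair, e.g. a terminal ``Minus_v`` meaning ``x - y``)
and whose internal nodes combine their two children.

Evaluation algebra
------------------
Values flowing through the tree are either vectors (dimension ``d`` of the
input pair) or scalars.

* leaves: ``x -> x``, ``y -> y``, terminal ``Plus_v -> x + y``,
  terminal ``Minus_v -> x - y``;
* internal vector operators (``Plus_v``, ``Minus_v``) act elementwise,
  broadcasting scalar children;
* internal scalar operators (``Plus_s``, ``Minus_s``, ``Multi_s``) act on
  scalar *reductions* of their children.  The default reduction of a vector
  ``v`` is its component sum ``sum_i v_i``; an alternative squared-norm
  reduction (``v . v``) is available through the ``reduction`` argument for
  sensitivity checks.
* a vector-valued root is reduced the same way.

The raw two-argument function this defines is not necessarily symmetric
(e.g. a ``Minus_v`` leaf), so :func:`gram` symmetrizes at the matrix level:
``K[i, j] = (k(x_i, z_j) + k(z_j, x_i)) / 2``.  Non-finite entries are
replaced by zero and flagged, which downstream fitness treats as a failed
kernel.  Positive semidefiniteness is *diagnosed* (:func:`mercer_check`),
not enforced; optional spectral clipping is provided for square Grams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import linear_kernel, polynomial_kernel, rbf_kernel

from .errors import InputError
from .symbols import Symbol, get_symbol

__all__ = [
    "KernelExpression",
    "BaselineKernelParams",
    "GramMatrix",
    "evaluate",
    "pairwise",
    "gram",
    "baseline_kernel",
    "baseline_gram",
    "mercer_check",
    "MercerReport",
]

REDUCTIONS = ("sum", "dot")


@dataclass(frozen=True)
class KernelExpression:
    """A node of a kernel parse tree: a symbol plus 0 or 2 children."""

    symbol: Symbol
    children: tuple["KernelExpression", ...] = ()

    def __post_init__(self) -> None:
        if len(self.children) not in (0, 2):
            raise InputError(
                f"kernel expression nodes take 0 or 2 children, got {len(self.children)}"
            )
        if not self.children and not self.symbol.may_be_terminal:
            raise InputError(
                f"scalar operator {self.symbol.name!r} cannot be a leaf"
            )
        if self.children and not self.symbol.is_operator:
            raise InputError(
                f"operand {self.symbol.name!r} cannot be an internal node"
            )

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def value_kind(self) -> str:
        """'scalar' for internal scalar-operator nodes, else 'vector'."""
        if self.children and self.symbol.is_scalar_op:
            return "scalar"
        return "vector"

    def size(self) -> int:
        """Number of nodes in the tree (equals chromosome gene count)."""
        return 1 + sum(c.size() for c in self.children)

    def depth(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + max(c.depth() for c in self.children)

    def to_prefix(self) -> str:
        """Nested prefix rendering, e.g. ``Plus_s(Multi_s(x,y), Minus_v)``."""
        if self.is_leaf:
            return self.symbol.name
        a, b = self.children
        return f"{self.symbol.name}({a.to_prefix()}, {b.to_prefix()})"

    @staticmethod
    def leaf(name: str) -> "KernelExpression":
        return KernelExpression(get_symbol(name))

    @staticmethod
    def node(name: str, left: "KernelExpression", right: "KernelExpression") -> "KernelExpression":
        return KernelExpression(get_symbol(name), (left, right))


@dataclass(frozen=True)
class BaselineKernelParams:
    """User parameters of the preset kernels: RBF width gamma, polynomial degree p."""

    gamma: float = 1.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise InputError(f"gamma must be positive, got {self.gamma}")
        if self.degree < 1:
            raise InputError(f"polynomial degree must be >= 1, got {self.degree}")


@dataclass
class GramMatrix:
    """A (possibly rectangular) kernel matrix with bookkeeping flags."""

    values: np.ndarray
    symmetrized: bool = True
    sanitized: bool = False
    row_ids: np.ndarray | None = None
    col_ids: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_square(self) -> bool:
        return self.values.shape[0] == self.values.shape[1]

    def to_text(self) -> str:
        """Dense text export with a one-line header (n, m, flags)."""
        n, m = self.values.shape
        header = f"# n={n} m={m} symmetrized={self.symmetrized} sanitized={self.sanitized}"
        body = "\n".join(" ".join(format(v, ".17g") for v in row) for row in self.values)
        return header + "\n" + body + "\n"


def _reduce(kind: str, value: np.ndarray, reduction: str) -> np.ndarray:
    if kind == "sca":
        return value
    if reduction == "sum":
        return value.sum(axis=-1)
    return (value * value).sum(axis=-1)  # "dot": v . v


def _eval_node(
    node: KernelExpression, xb: np.ndarray, yb: np.ndarray, reduction: str
) -> tuple[str, np.ndarray]:
    """Recursive broadcast evaluation; returns (kind, array).

    ``xb``/``yb`` carry the batched input pair with a trailing feature axis;
    ``kind`` is 'vec' (array keeps the feature axis) or 'sca'.
    """
    name = node.symbol.name
    if node.is_leaf:
        if name == "x":
            return "vec", xb
        if name == "y":
            return "vec", yb
        if name == "Plus_v":
            return "vec", xb + yb
        # Minus_v: the only remaining legal leaf
        return "vec", xb - yb
    ka, va = _eval_node(node.children[0], xb, yb, reduction)
    kb, vb = _eval_node(node.children[1], xb, yb, reduction)
    if node.symbol.is_vector_op:
        # elementwise; scalar children broadcast along the feature axis
        if ka == "sca" and kb == "vec":
            va = va[..., None]
        elif kb == "sca" and ka == "vec":
            vb = vb[..., None]
        kind = "vec" if "vec" in (ka, kb) else "sca"
        return kind, (va + vb) if name == "Plus_v" else (va - vb)
    ra = _reduce(ka, va, reduction)
    rb = _reduce(kb, vb, reduction)
    if name == "Plus_s":
        return "sca", ra + rb
    if name == "Minus_s":
        return "sca", ra - rb
    return "sca", ra * rb  # Multi_s


def evaluate(
    expr: KernelExpression,
    x: np.ndarray,
    y: np.ndarray,
    reduction: str = "sum",
) -> float:
    """Evaluate ``expr`` on a single ordered pair of feature vectors.

    Returns the *raw* (unsymmetrized) value; ``gram`` handles symmetry.
    """
    if reduction not in REDUCTIONS:
        raise InputError(f"unknown reduction {reduction!r}; valid: {REDUCTIONS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise InputError(f"x and y must be equal-length vectors, got {x.shape} and {y.shape}")
    with np.errstate(over="ignore", invalid="ignore"):
        kind, value = _eval_node(expr, x, y, reduction)
        out = _reduce(kind, value, reduction)
    return float(out)


def pairwise(
    expr: KernelExpression,
    X: np.ndarray,
    Z: np.ndarray,
    reduction: str = "sum",
) -> np.ndarray:
    """Raw kernel values for all ordered pairs: ``R[i, j] = k(X_i, Z_j)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise InputError(
            f"feature dimensions differ: X has {X.shape[1]}, Z has {Z.shape[1]}"
        )
    xb = X[:, None, :]  # (n, 1, d)
    zb = Z[None, :, :]  # (1, m, d)
    with np.errstate(over="ignore", invalid="ignore"):
        kind, value = _eval_node(expr, xb, zb, reduction)
        out = _reduce(kind, value, reduction)
        out = np.broadcast_to(out, (X.shape[0], Z.shape[0])).astype(float, copy=True)
    return out


def gram(
    expr: KernelExpression,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    reduction: str = "sum",
    clip_negative_eigenvalues: bool = False,
) -> GramMatrix:
    """Symmetrized, sanitized kernel matrix between row sets ``X`` and ``Z``.

    ``K[i, j] = (k(X_i, Z_j) + k(Z_j, X_i)) / 2``; non-finite entries are
    replaced by 0 and the ``sanitized`` flag set.  With
    ``clip_negative_eigenvalues`` a *square* Gram is projected onto the PSD
    cone (negative eigenvalues zeroed), an optional Mercer repair.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Zm = X if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    r1 = pairwise(expr, X, Zm, reduction)
    r2 = pairwise(expr, Zm, X, reduction)
    with np.errstate(over="ignore", invalid="ignore"):
        K = 0.5 * (r1 + r2.T)
    bad = ~np.isfinite(K)
    sanitized = bool(bad.any())
    if sanitized:
        K = np.where(bad, 0.0, K)
    if clip_negative_eigenvalues:
        if K.shape[0] != K.shape[1]:
            raise InputError("spectral clipping requires a square Gram")
        w, v = np.linalg.eigh(0.5 * (K + K.T))
        if w.min() < 0:
            K = (v * np.clip(w, 0.0, None)) @ v.T
            K = 0.5 * (K + K.T)
    return GramMatrix(values=K, symmetrized=True, sanitized=sanitized)


def baseline_kernel(
    name: str,
    x: np.ndarray,
    y: np.ndarray,
    params: BaselineKernelParams | None = None,
) -> float:
    """One of the preset kernels on a single pair.

    ``linear``: ``x . y``;  ``polynomial``: ``(x . y + 1)^p``;
    ``rbf``: ``exp(-gamma * |x - y|^2)``.
    """
    return float(baseline_gram(name, np.atleast_2d(x), np.atleast_2d(y), params)[0, 0])


def baseline_gram(
    name: str,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    params: BaselineKernelParams | None = None,
) -> np.ndarray:
    """Preset-kernel matrix between row sets, delegating to scikit-learn."""
    params = params or BaselineKernelParams()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Zm = X if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Zm.shape[1]:
        raise InputError(
            f"feature dimensions differ: X has {X.shape[1]}, Z has {Zm.shape[1]}"
        )
    if name == "linear":
        return linear_kernel(X, Zm)
    if name == "polynomial":
        return polynomial_kernel(X, Zm, degree=params.degree, gamma=1.0, coef0=1.0)
    if name == "rbf":
        return rbf_kernel(X, Zm, gamma=params.gamma)
    raise InputError(f"unknown baseline kernel {name!r}; valid: linear, polynomial, rbf")


@dataclass(frozen=True)
class MercerReport:
    psd: bool
    min_eigenvalue: float


def mercer_check(g: GramMatrix | np.ndarray, tol: float = 1e-8) -> MercerReport:
    """Diagnose positive semidefiniteness of a square symmetric Gram.

    ``psd`` is true when the smallest eigenvalue is >= ``-tol``.  An evolved
    kernel need not be a Mercer kernel; this reports whether the SVM dual on
    this particular Gram is convex.
    """
    K = g.values if isinstance(g, GramMatrix) else np.asarray(g, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise InputError(f"mercer_check needs a square matrix, got shape {K.shape}")
    w = np.linalg.eigvalsh(0.5 * (K + K.T))
    wmin = float(w.min())
    return MercerReport(psd=wmin >= -tol, min_eigenvalue=wmin)
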