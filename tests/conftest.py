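"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive behaviour from first principles
(plain recursive tree construction and evaluation, brute-force pair
counting) so they stay independent of the code paths they check.
"""

import numpy as np
import pytest

from genefold.chromosome import Chromosome, random_chromosome
from genefold.data_io import encode_labels, minmax_scale, synth_dataset
from genefold.evolution import GFConfig


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_build(symbols, folds, i=0):
    """Brute-force recursive tree builder: nested tuples (symbol, left, right)."""
    left, right = (int(p) for p in folds[i].split("."))
    if left == 0 and right == i:
        return (symbols[i],)
    return (symbols[i], oracle_build(symbols, folds, left), oracle_build(symbols, folds, right))


def tree_as_tuple(expr):
    """Convert a KernelExpression into the oracle's nested-tuple form."""
    if expr.is_leaf:
        return (expr.symbol.name,)
    a, b = expr.children
    return (expr.symbol.name, tree_as_tuple(a), tree_as_tuple(b))


def oracle_evaluate(expr, x, y, reduction="sum"):
    """Direct recursive interpreter of the kernel algebra (scalar path only)."""

    def red(v):
        if isinstance(v, np.ndarray):
            return float(np.sum(v)) if reduction == "sum" else float(np.dot(v, v))
        return v

    def ev(node):
        s = node.symbol.name
        if node.is_leaf:
            return {"x": x, "y": y, "Plus_v": x + y, "Minus_v": x - y}[s]
        a, b = ev(node.children[0]), ev(node.children[1])
        if s == "Plus_v":
            return a + b
        if s == "Minus_v":
            return a - b
        ra, rb = red(a), red(b)
        return {"Plus_s": ra + rb, "Minus_s": ra - rb, "Multi_s": ra * rb}[s]

    with np.errstate(over="ignore", invalid="ignore"):
        return red(ev(expr))


def enumerate_structures(n):
    """All valid fold structures of exactly n genes (brute force with checks)."""
    out = []

    def spanning_ok(folds):
        ref = [0] * n
        for j, (a, b) in enumerate(folds):
            if not (a == 0 and b == j):
                ref[a] += 1
                ref[b] += 1
        if ref[0] != 0 or any(ref[j] != 1 for j in range(1, n)):
            return False
        seen = set()
        stack = [0]
        while stack:
            j = stack.pop()
            if j in seen:
                return False
            seen.add(j)
            a, b = folds[j]
            if not (a == 0 and b == j):
                stack += [a, b]
        return len(seen) == n

    def gen(i, folds):
        if i == n:
            if spanning_ok(folds):
                out.append(tuple(folds))
            return
        options = [(0, i)]
        for a in range(i + 1, n):
            for b in range(i + 1, n):
                if a != b:
                    options.append((a, b))
        for o in options:
            folds.append(o)
            gen(i + 1, folds)
            folds.pop()

    gen(0, [])
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def separable_table():
    """Well-separated two-Gaussian table (n=200, d=8), scaled and encoded."""
    return encode_labels(minmax_scale(synth_dataset(200, 8, separation=6.0, seed=7)))


@pytest.fixture(scope="session")
def null_table():
    """Zero-separation table: labels carry no information."""
    return encode_labels(minmax_scale(synth_dataset(200, 8, separation=0.0, seed=7)))


@pytest.fixture
def small_config():
    return GFConfig(population_size=10, generations=3, head_length=5, seed=11)


def random_valid_chromosomes(count, seed=0, head_length=6):
    """A stream of random valid chromosomes of varying head lengths."""
    rng = np.random.default_rng(seed)
    cfg = GFConfig(head_length=head_length, seed=seed)
    return [random_chromosome(cfg, rng) for _ in range(count)]


# Typed-in sample rows of the prostate feature table schema
# (8 morphology features + M/B diagnosis) used to exercise the loader.
PROSTATE_SAMPLE_CSV = """\
Radius,Texture,Perimeter,Area,Smoothness,Compactness,Symmetry,Fractal_dimension,Diagnosis
23,12,151,954,0.143,0.278,0.242,0.079,M
9,13,133,1326,0.143,0.079,0.181,0.057,B
21,27,130,1203,0.125,0.16,0.207,0.06,M
14,16,78,386,0.07,0.284,0.26,0.097,M
9,19,135,1297,0.141,0.133,0.181,0.059,M
25,25,83,477,0.128,0.17,0.209,0.076,B
16,26,120,1040,0.095,0.109,0.179,0.057,M
15,18,90,578,0.119,0.165,0.22,0.075,M
19,24,88,520,0.127,0.193,0.235,0.074,M
25,11,84,476,0.119,0.24,0.203,0.082,M
"""

# First columns of the breast cancer (WDBC-style) schema; a diagnosis
# column is appended because the loader requires one.
BREAST_SAMPLE_CSV = """\
Radius,Texture,Perimeter,Area,Smoothness,Compactness,Concavity,Diagnosis
20.57,17.77,132.90,1326.0,0.08,0.08,0.09,M
19.69,21.25,130.00,1203.0,0.11,0.16,0.20,M
20.29,14.34,135.10,1297.0,0.10,0.13,0.20,M
12.45,15.70,82.57,477.10,0.13,0.17,0.16,M
18.25,19.98,119.60,1040.0,0.09,0.11,0.11,M
13.71,20.83,90.20,577.90,0.12,0.16,0.09,M
"""
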