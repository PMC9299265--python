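"""Genotype tests: decoding, encoding, validation, random generation."""

import numpy as np
import pytest

from conftest import (
    enumerate_structures,
    oracle_build,
    random_valid_chromosomes,
    tree_as_tuple,
)
from genefold.chromosome import (
    Chromosome,
    FoldIndex,
    complexity,
    decode,
    encode,
    random_chromosome,
    rebuild_from_symbols,
    validate,
)
from genefold.errors import (
    GenerationError,
    InvalidTerminalError,
    MalformedChromosomeError,
    SpanningTreeError,
)
from genefold.evolution import GFConfig
from genefold.reference_kernels import breast_chromosome, prostate_chromosome
from genefold.symbols import SCALAR_OPERATORS, SYMBOLS, TERMINAL_SYMBOLS


class TestFoldIndex:
    def test_serialization_matches_printed_dialect(self):
        assert str(FoldIndex(1, 2)) == "1.2"
        assert str(FoldIndex(0, 14)) == "0.14"
        assert FoldIndex.parse("0.14") == FoldIndex(0, 14)

    @pytest.mark.parametrize("bad", ["1,2", "1.", "a.b", "1.2.3", "-1.2"])
    def test_rejects_malformed_text(self, bad):
        with pytest.raises(MalformedChromosomeError):
            FoldIndex.parse(bad)


class TestDecode:
    def test_worked_example_five_genes(self):
        """The canonical 5-gene worked example decodes by the child-indexing rule."""
        tree = decode(
            ["Minus_s", "Plus_s", "y", "y", "x"],
            ["1.2", "3.4", "0.2", "0.3", "0.4"],
        )
        assert tree.to_prefix() == "Minus_s(Plus_s(y, x), y)"
        assert tree_as_tuple(tree) == oracle_build(
            ["Minus_s", "Plus_s", "y", "y", "x"], ["1.2", "3.4", "0.2", "0.3", "0.4"]
        )

    def test_breast_reference_chromosome_structure(self):
        c = breast_chromosome()
        tree = decode(c.symbols(), c.folds())
        assert tree.size() == 15
        assert tree.symbol.name == "Plus_s"
        # root children decoded at positions 1 and 2
        assert tree.children[0].symbol.name == "Plus_s"
        assert tree.children[1].symbol.name == "x"
        # leaves: positions 2, 6, 9-14; positions 6, 10, 14 are terminal Minus_v
        leaf_names = sorted(
            n.symbol.name for n in _iter_nodes(tree) if n.is_leaf
        )
        assert leaf_names == ["Minus_v", "Minus_v", "Minus_v", "x", "x", "x", "x", "x"]

    def test_prostate_reference_chromosome_structure(self):
        c = prostate_chromosome()
        tree = decode(c.symbols(), c.folds())
        assert tree.size() == 27
        assert tree.symbol.name == "Plus_s"
        assert validate(c).ok

    def test_out_of_range_child_names_position(self):
        with pytest.raises(MalformedChromosomeError, match="gene 0"):
            decode(["Plus_s", "x", "x"], ["5.6", "0.1", "0.2"])

    def test_backward_reference_rejected(self):
        with pytest.raises(MalformedChromosomeError, match="backward"):
            decode(
                ["Plus_s", "Plus_s", "x", "x", "x"],
                ["1.2", "0.3", "3.4", "0.3", "0.4"],
            )

    def test_scalar_operator_terminal_rejected(self):
        with pytest.raises(InvalidTerminalError):
            decode(["Plus_s", "Multi_s", "x"], ["1.2", "0.1", "0.2"])

    def test_doubly_referenced_gene_rejected(self):
        with pytest.raises(SpanningTreeError):
            decode(["Plus_s", "x", "x"], ["1.1", "0.1", "0.2"])

    def test_unreferenced_gene_rejected(self):
        with pytest.raises(SpanningTreeError):
            decode(["Plus_s", "x", "x", "x"], ["1.2", "0.1", "0.2", "0.3"])

    def test_exhaustive_small_chromosomes_match_recursive_oracle(self):
        """decode agrees with a brute-force recursive builder on every valid
        structure of 1, 3, 5 and 7 genes (symbols exhausted up to 5 genes,
        cycled deterministically at 7)."""
        from itertools import product

        internal_pool = list(SCALAR_OPERATORS) + ["Plus_v", "Minus_v"]
        leaf_pool = list(TERMINAL_SYMBOLS)
        checked = 0
        for n in (1, 3, 5, 7):
            for structure in enumerate_structures(n):
                folds = [
                    f"{a}.{b}" for (a, b) in structure
                ]
                internal_pos = [i for i, (a, b) in enumerate(structure) if not (a == 0 and b == i)]
                leaf_pos = [i for i in range(n) if i not in internal_pos]
                if n <= 5:
                    symbol_choices = product(
                        product(internal_pool, repeat=len(internal_pos)),
                        product(leaf_pool, repeat=len(leaf_pos)),
                    )
                else:
                    symbol_choices = [
                        (
                            tuple(internal_pool[(k + j) % len(internal_pool)] for j in range(len(internal_pos))),
                            tuple(leaf_pool[(k + j) % len(leaf_pool)] for j in range(len(leaf_pos))),
                        )
                        for k in range(len(internal_pool) * len(leaf_pool))
                    ]
                for internal_syms, leaf_syms in symbol_choices:
                    symbols = [""] * n
                    for i, s in zip(internal_pos, internal_syms):
                        symbols[i] = s
                    for i, s in zip(leaf_pos, leaf_syms):
                        symbols[i] = s
                    assert tree_as_tuple(decode(symbols, folds)) == oracle_build(symbols, folds)
                    checked += 1
        assert checked > 30_000


class TestEncode:
    def test_single_leaf(self):
        from genefold.kernel import KernelExpression

        symbols, folds = encode(KernelExpression.leaf("x"))
        assert symbols == ["x"] and folds == ["0.0"]

    def test_worked_example_roundtrip(self):
        symbols = ["Minus_s", "Plus_s", "y", "y", "x"]
        folds = ["1.2", "3.4", "0.2", "0.3", "0.4"]
        tree = decode(symbols, folds)
        s2, f2 = encode(tree)
        assert s2 == symbols  # breadth-first layout reproduces the printed order
        assert tree_as_tuple(decode(s2, f2)) == tree_as_tuple(tree)

    @pytest.mark.parametrize("reference", [prostate_chromosome, breast_chromosome])
    def test_reference_chromosomes_roundtrip(self, reference):
        c = reference()
        tree = decode(c.symbols(), c.folds())
        s2, f2 = encode(tree)
        assert tree_as_tuple(decode(s2, f2)) == tree_as_tuple(tree)

    def test_random_roundtrip_is_identity(self):
        for c in random_valid_chromosomes(200, seed=3):
            tree = decode(c.symbols(), c.folds())
            s2, f2 = encode(tree)
            assert tree_as_tuple(decode(s2, f2)) == tree_as_tuple(tree)


class TestValidate:
    @pytest.mark.parametrize("reference", [prostate_chromosome, breast_chromosome])
    def test_reference_chromosomes_pass(self, reference):
        report = validate(reference())
        assert report.ok and report.violations == []

    def test_broken_reference_pattern_detected_not_raised(self):
        # gene 2's "0.1" re-references gene 1 and leaves gene 2 unreachable:
        # diagnosed as a structural violation, never raised
        c = Chromosome.from_lists(["Plus_s", "x", "x"], ["1.2", "0.1", "0.1"])
        report = validate(c)
        assert not report.ok and report.violations

    def test_double_reference_detected_not_raised(self):
        c = Chromosome.from_lists(
            ["Plus_s", "Plus_s", "x", "x", "x"],
            ["1.2", "3.3", "0.2", "0.3", "0.4"],
        )
        report = validate(c)
        assert not report.ok
        assert any("referenced by 2 parents" in v for v in report.violations)

    def test_out_of_range_detected(self):
        c = Chromosome.from_lists(["Plus_s", "x", "x"], ["5.6", "0.1", "0.2"])
        report = validate(c)
        assert not report.ok and any("out of range" in v for v in report.violations)

    def test_operand_in_head_detected(self):
        c = Chromosome.from_lists(["Plus_s", "x", "x"], ["1.2", "0.1", "0.2"], head_length=2)
        report = validate(c)
        assert not report.ok and any("head" in v for v in report.violations)


class TestRandomChromosome:
    def test_minimal_head_gives_three_genes(self, rng):
        cfg = GFConfig(head_length=1)
        c = random_chromosome(cfg, rng)
        assert len(c) == 3
        assert c.genes[0].symbol.is_operator
        assert validate(c).ok

    def test_thousand_draws_all_valid_and_capped(self):
        rng = np.random.default_rng(42)
        cfg = GFConfig(head_length=10, gene_cap=50)
        for _ in range(1000):
            c = random_chromosome(cfg, rng)
            assert validate(c).ok
            assert 3 <= len(c) <= cfg.gene_cap
            head = c.genes[: c.head_length]
            assert all(g.symbol.is_operator for g in head)

    def test_fixed_seed_reproduces(self):
        cfg = GFConfig(head_length=8)
        a = random_chromosome(cfg, np.random.default_rng(5))
        b = random_chromosome(cfg, np.random.default_rng(5))
        assert a.key() == b.key()

    def test_impossible_cap_raises(self, rng):
        with pytest.raises(GenerationError):
            random_chromosome(GFConfig(gene_cap=2), rng)


class TestSerialization:
    def test_bracketed_roundtrip(self):
        c = prostate_chromosome()
        text = c.to_bracketed()
        c2 = Chromosome.from_bracketed(text)
        assert c2.key() == c.key()
        # dialect check: period separator, no padding, quoted entries
        assert "'0.9'" in text and "'Plus_s'" in text

    def test_json_roundtrip(self):
        c = breast_chromosome()
        c2 = Chromosome.from_json(c.to_json(fitness=0.99, dataset="breast", seed=1))
        assert c2.key() == c.key()

    def test_rebuild_drops_unreachable_tail(self, rng):
        # an operand at the root closes immediately; the tail is dropped
        c = rebuild_from_symbols(["x", "Plus_s", "x", "x"], rng)
        assert len(c) == 1 and validate(c).ok


def test_complexity_counts_genes():
    assert complexity(prostate_chromosome()) == 27
    assert complexity(breast_chromosome()) == 15
    assert complexity(Chromosome.from_lists(["x"], ["0.0"])) == 1


def test_symbol_table_matches_published_vocabulary():
    """Seven symbols with published arity metadata (decoder ignores arity)."""
    assert set(SYMBOLS) == {"Plus_s", "Minus_s", "Multi_s", "Plus_v", "Minus_v", "x", "y"}
    assert all(SYMBOLS[s].arity == 1 for s in ("Plus_s", "Minus_s", "Multi_s", "x", "y"))
    assert all(SYMBOLS[s].arity == 2 for s in ("Plus_v", "Minus_v"))


def _iter_nodes(tree):
    yield tree
    for c in tree.children:
        yield from _iter_nodes(c)
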