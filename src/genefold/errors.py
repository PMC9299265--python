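"""Exception hierarchy for genefold.

All package-specific failures derive from :class:`GenefoldError` so callers
(and the CLI) can distinguish user/data errors from genuine bugs.
"""


class GenefoldError(Exception):
    """Base class for all genefold errors."""


class MalformedChromosomeError(GenefoldError):
    """A chromosome's folding indices are structurally broken.

    Raised for out-of-range child positions, backward references
    (child position <= parent position) and operands used as internal
    nodes.  The message names the offending gene position.
    """


class InvalidTerminalError(GenefoldError):
    """A scalar operator was placed in a terminal (leaf) position."""


class SpanningTreeError(GenefoldError):
    """The folding indices do not form a tree spanning every gene.

    Either some gene is referenced by more than one parent, or some gene
    is unreachable from the root, or a cycle was detected.
    """


class GenerationError(GenefoldError):
    """Random chromosome generation is impossible under the configuration."""


class ConfigError(GenefoldError):
    """An evolution / run configuration violates its invariants."""


class InputError(GenefoldError):
    """Invalid data passed to a numeric operation (shapes, classes, ranges)."""


class TransformError(GenefoldError):
    """A preprocessing transform cannot be applied to the given table."""


class TableParseError(GenefoldError):
    """A feature-table file could not be parsed (bad label, non-numeric cell)."""
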