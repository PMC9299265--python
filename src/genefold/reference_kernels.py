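"""Reference evolved kernel genotypes for the two cancer-detection tasks.

These are the best chromosomes reported by the Genetic Folding study this
package implements: a 27-gene kernel evolved on the prostate-cancer table
(8 features, 100 patients) and a 15-gene kernel evolved on the Wisconsin
diagnostic breast-cancer table (30 features, 569 samples).  They double as
ground-truth fixtures for the decoder: both must decode into spanning
trees, round-trip through encode/decode, and produce finite symmetric Gram
matrices.
"""

from .chromosome import Chromosome

PROSTATE_SYMBOLS = [
    "Plus_s", "Multi_s", "Multi_s", "Plus_s", "Minus_s", "Minus_v", "Minus_v",
    "Plus_s", "Plus_s", "x", "Minus_s", "Plus_v", "Plus_v", "Plus_v", "x",
    "Plus_s", "Minus_s", "Minus_v", "Minus_v", "Minus_v", "x", "x", "x", "x",
    "x", "x", "x",
]

PROSTATE_FOLDS = [
    "1.2", "3.4", "5.6", "7.8", "9.10", "0.5", "0.6", "11.12", "13.14", "0.9",
    "15.16", "17.18", "19.20", "21.22", "0.14", "23.24", "25.26", "0.17",
    "0.18", "0.19", "0.20", "0.21", "0.22", "0.23", "0.24", "0.25", "0.26",
]

BREAST_SYMBOLS = [
    "Plus_s", "Plus_s", "x", "Plus_s", "Multi_s", "Multi_s", "Minus_v",
    "Plus_s", "Plus_s", "x", "Minus_v", "x", "x", "x", "Minus_v",
]

BREAST_FOLDS = [
    "1.2", "3.4", "0.2", "5.6", "7.8", "9.10", "0.6", "11.12", "13.14", "0.9",
    "0.10", "0.11", "0.12", "0.13", "0.14",
]


def prostate_chromosome() -> Chromosome:
    """The 27-gene best kernel genotype for the prostate dataset."""
    return Chromosome.from_lists(PROSTATE_SYMBOLS, PROSTATE_FOLDS)


def breast_chromosome() -> Chromosome:
    """The 15-gene best kernel genotype for the breast dataset."""
    return Chromosome.from_lists(BREAST_SYMBOLS, BREAST_FOLDS)
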