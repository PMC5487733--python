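"""Shared constants, genetic-code tables and exception types."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

#: codon -> one-letter amino acid, '*' for stops
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"

SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"))

ALL_CODONS = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)

#: The nine single-mismatch neighbours of ATG. The subset observed to act as
#: initiators in fungal leaders (AUC, ACG, AUU, CUG, UUG, GUG, AUA) is
#: contained in it; filtering is identical either way.
DEFAULT_NCC_SET = ("ATA", "ATC", "ATT", "ACG", "AAG", "AGG", "CTG", "GTG", "TTG")

GAP_CODON = "---"


class ExtorfError(Exception):
    """Base class for package errors."""


class InvalidInputError(ExtorfError):
    pass


class InvalidRegionError(ExtorfError):
    pass


class FrameError(ExtorfError):
    pass


class GenerationError(ExtorfError):
    """Synthetic-data rejection sampling exhausted its attempt budget."""
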