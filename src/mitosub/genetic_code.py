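"""Vertebrate-mitochondrial genetic code and substitution classification.

The vertebrate mitochondrial code (NCBI translation table 2) differs from
the standard code at four codons: ATA encodes Met, TGA encodes Trp, and
AGA/AGG are stop codons.  Stop is treated as a 21st amino-acid level
throughout, so a change into or out of a stop codon is simply
non-synonymous.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

STOP = "*"

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]


def _build_code() -> dict[str, str]:
    code = dict(_MITO_TABLE.forward_table)
    for stop_codon in _MITO_TABLE.stop_codons:
        code[stop_codon] = STOP
    return code


#: codon -> one-letter amino acid (``*`` for stop), vertebrate mitochondrial
MITO_CODE: dict[str, str] = _build_code()

ALL_CODONS = ["".join(c) for c in product(BASES, repeat=3)]


def codon_index(codon: str) -> int:
    """Pack a codon into an integer in ``range(64)`` (base-4, A=0..T=3)."""
    return 16 * BASE_INDEX[codon[0]] + 4 * BASE_INDEX[codon[1]] + BASE_INDEX[codon[2]]


def codon_from_index(idx: int) -> str:
    return BASES[idx // 16] + BASES[(idx // 4) % 4] + BASES[idx % 4]


class InvalidCodonError(ValueError):
    pass


def translate_codon(codon: str) -> str:
    """Translate a codon under the vertebrate mitochondrial code.

    Returns a one-letter amino-acid symbol, with ``"*"`` for stop.
    Raises :class:`InvalidCodonError` on anything but a 3-mer over ACGT.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASE_INDEX for b in codon):
        raise InvalidCodonError(f"not a valid ACGT codon: {codon!r}")
    return MITO_CODE[codon]


def classify_change(from_base: str, to_base: str) -> str:
    """Classify a base change as ``"ts"`` (transition) or ``"tv"`` (transversion)."""
    a, b = from_base.upper(), to_base.upper()
    if a == b:
        raise ValueError(f"not a substitution: {a} -> {b}")
    for base in (a, b):
        if base not in BASE_INDEX:
            raise ValueError(f"invalid base: {base!r}")
    same_class = (a in PURINES) == (b in PURINES)
    return "ts" if same_class else "tv"


@dataclass(frozen=True)
class PossibleSubCounts:
    """Counts of the 3 possible single-base changes at one codon position.

    Exactly one of the three alternative bases is a transition and two are
    transversions, so ``syn_ts + nonsyn_ts == 1`` and
    ``syn_tv + nonsyn_tv == 2`` always hold.
    """

    syn_ts: int
    syn_tv: int
    nonsyn_ts: int
    nonsyn_tv: int

    @property
    def syn(self) -> int:
        return self.syn_ts + self.syn_tv

    @property
    def nonsyn(self) -> int:
        return self.nonsyn_ts + self.nonsyn_tv


def possible_sub_counts(codon: str, position: int) -> PossibleSubCounts:
    """Classify the three possible substitutions at ``position`` (1-based) of ``codon``.

    Synonymy is judged under the mitochondrial code with stop as an ordinary
    21st symbol: any change between a stop codon and a coding codon is
    non-synonymous.
    """
    codon = codon.upper()
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position}")
    aa = translate_codon(codon)
    counts = {"syn_ts": 0, "syn_tv": 0, "nonsyn_ts": 0, "nonsyn_tv": 0}
    old = codon[position - 1]
    for alt in BASES:
        if alt == old:
            continue
        new_codon = codon[: position - 1] + alt + codon[position:]
        syn = "syn" if translate_codon(new_codon) == aa else "nonsyn"
        counts[f"{syn}_{classify_change(old, alt)}"] += 1
    return PossibleSubCounts(**counts)


def _possible_counts_table() -> list[list[PossibleSubCounts]]:
    return [
        [possible_sub_counts(codon_from_index(i), pos) for pos in (1, 2, 3)]
        for i in range(64)
    ]


#: POSSIBLE_COUNTS[codon_index][position-1] -> PossibleSubCounts
POSSIBLE_COUNTS: list[list[PossibleSubCounts]] = _possible_counts_table()

#: AA_BY_CODON_INDEX[codon_index] -> amino-acid symbol
AA_BY_CODON_INDEX: list[str] = [MITO_CODE[codon_from_index(i)] for i in range(64)]
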