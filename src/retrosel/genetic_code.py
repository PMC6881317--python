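"""Sense-codon state space and precomputed substitution classifications.

The codon model operates on the 61 sense codons of the standard genetic
code; stop codons have no state.  Everything here is derived once, at
import, from Biopython's standard codon table.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
_PURINES = {"A", "G"}

_table = CodonTable.unambiguous_dna_by_name["Standard"]

STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(
        "".join(c)
        for c in itertools.product(NUCLEOTIDES, repeat=3)
        if "".join(c) not in STOP_CODONS
    )
)
N_STATES = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF_CODON: dict[str, str] = {c: _table.forward_table[c] for c in SENSE_CODONS}
AA_ARRAY = np.array([AA_OF_CODON[c] for c in SENSE_CODONS])


def is_transition(a: str, b: str) -> bool:
    """True for A<->G and C<->T nucleotide changes."""
    return a != b and (a in _PURINES) == (b in _PURINES)


def _classify_pairs():
    i_idx, j_idx, ts, syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            i_idx.append(i)
            j_idx.append(j)
            ts.append(is_transition(ci[p], cj[p]))
            syn.append(AA_OF_CODON[ci] == AA_OF_CODON[cj])
    return (
        np.array(i_idx, dtype=np.intp),
        np.array(j_idx, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


# Ordered pairs of sense codons one nucleotide apart, with transition and
# synonymy flags; the single lookup every rate matrix is built from.
PAIR_I, PAIR_J, PAIR_IS_TS, PAIR_IS_SYN = _classify_pairs()


def is_sense_codon(codon: str) -> bool:
    return codon in CODON_INDEX


def translate_codon(codon: str) -> str:
    """Amino acid of a sense codon, '*' for stops, 'X' otherwise."""
    if codon in CODON_INDEX:
        return AA_OF_CODON[codon]
    if codon in STOP_CODONS:
        return "*"
    return "X"
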