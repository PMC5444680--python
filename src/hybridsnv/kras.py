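"""The KRAS exon-2 codon 12/13 hotspot panel.

The assay targets the 23-nt region around KRAS codons 12 and 13.  The target
strand stored here is the strand that hybridizes to the array probes:

    5'-TTGCCTACGCCACCAGCTCCAAC-3'

so the perfect-match probe reads 3'-AACGGATGCGGTGGTCGAGGTTG-5' when written
against it.  The panel's customary nucleotide position counters (9-13) run in
the opposite direction along this strand: counter ``c`` is target index
``23 - c``.  For example ``10C→G`` (amino-acid notation G12A) substitutes G at
target index 13.
"""

from __future__ import annotations

from .probeset import (
    MutationHypothesis,
    Probeset,
    TargetSequence,
    design_probeset,
    enumerate_hypotheses,
    parse_label,
)

KRAS_TARGET = TargetSequence("TTGCCTACGCCACCAGCTCCAAC", name="KRAS_ex2_c12_13")

#: printed position counters of the panel (codon 12: 9, 10; codon 13: 12, 13)
PANEL_COUNTERS = (9, 10, 12, 13)


def target_index(counter: int) -> int:
    """Target-strand 1-based index for a panel position counter."""
    return 23 - counter


def position_counter(index: int) -> int:
    """Panel position counter for a target-strand index."""
    return 23 - index


#: target-strand coordinates of the four hotspot positions
PANEL_POSITIONS = tuple(sorted(target_index(c) for c in PANEL_COUNTERS))

#: amino-acid aliases of the 12 most commonly reported exon-2 KRAS mutations
AA_ALIASES = {
    "9C→A": "G12C",
    "9C→T": "G12S",
    "9C→G": "G12R",
    "10C→T": "G12D",
    "10C→G": "G12A",
    "10C→A": "G12V",
    "12C→A": "G13C",
    "12C→T": "G13S",
    "12C→G": "G13R",
    "13C→T": "G13D",
    "13C→G": "G13A",
    "13C→A": "G13V",
}


def kras_panel() -> list[MutationHypothesis]:
    """The 12 panel hypotheses, three substitutions at each hotspot position."""
    return enumerate_hypotheses(
        KRAS_TARGET,
        PANEL_POSITIONS,
        counter_map=position_counter,
        aa_aliases=AA_ALIASES,
    )


def kras_hypothesis(label: str) -> MutationHypothesis:
    """Look up one panel hypothesis from its label, e.g. ``"10C→G"`` or ``"10C>G"``."""
    counter, wt, alt = parse_label(label)
    for h in kras_panel():
        if h.position == target_index(counter) and h.alt_base == alt and h.wt_base == wt:
            return h
    raise KeyError(f"{label!r} is not one of the 12 KRAS panel mutations")


def default_probeset(edge_margin: int = 4, min_separation: int = 5) -> Probeset:
    """The PM/1MM/2MM probeset of the KRAS assay (541 probes at defaults)."""
    return design_probeset(KRAS_TARGET, edge_margin=edge_margin, min_separation=min_separation)
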