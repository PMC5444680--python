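"""Mismatch-probeset design and candidate point-mutation hypotheses.

A hybridization array for single-nucleotide-variant screening tiles one
perfect-match (PM) probe against a short wild-type target plus every probe
carrying one or two deliberate internal mismatches (1MM/2MM).  Each candidate
point mutation then maps onto the subset of probes whose engineered variant
pairs the mutant base perfectly (the *mutation branch*) and the subset that
varies at the same position but with a different base (the *side branch*).

Coordinates are 1-based on the target strand in its 5'->3' orientation.
Probes are stored in their own 5'->3' frame (the reverse complement of the
mutated target), while all mismatch positions refer to target coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# right arrow used in mutation labels; ">" is accepted on input
ARROW = "→"


class HybridSNVError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(HybridSNVError):
    pass


class ProbesetDesignError(HybridSNVError):
    pass


class UncoveredPositionError(HybridSNVError):
    pass


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class TargetSequence:
    """A short single-stranded wild-type target region, 5'->3'."""

    bases: str
    name: str = "target"

    def __post_init__(self) -> None:
        if not set(self.bases) <= DNA_ALPHABET or not self.bases:
            raise InvalidSequenceError(
                f"target {self.name!r} must be non-empty over {{A,C,G,T}}"
            )
        if len(self.bases) < 7:
            raise InvalidSequenceError(
                f"target {self.name!r} is {len(self.bases)} nt; need >= 7 for an interior mismatch"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def base_at(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self.bases):
            raise IndexError(f"position {position} outside 1..{len(self.bases)}")
        return self.bases[position - 1]

    def with_mutations(self, mutations: Iterable[tuple[int, str]]) -> "TargetSequence":
        """Return a copy carrying the given (position, alt_base) substitutions."""
        seq = list(self.bases)
        tags = []
        for pos, alt in sorted(mutations):
            wt = self.base_at(pos)
            if alt == wt:
                raise InvalidSequenceError(f"{pos}{wt}{ARROW}{alt} is not a substitution")
            if alt not in DNA_ALPHABET:
                raise InvalidSequenceError(f"invalid base {alt!r}")
            seq[pos - 1] = alt
            tags.append(f"{pos}{wt}{ARROW}{alt}")
        name = self.name + ("_" + ",".join(tags) if tags else "")
        return TargetSequence("".join(seq), name=name)


@dataclass(frozen=True)
class Probe:
    """One array probe.

    ``bases`` is the probe strand 5'->3'; it is the reverse complement of the
    target after applying the recorded mismatches.  ``mismatches`` holds
    ``(position, variant_base)`` pairs in target coordinates: the probe pairs
    perfectly with a target carrying ``variant_base`` at ``position``.
    """

    bases: str
    mismatches: tuple[tuple[int, str], ...] = ()

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatches)

    @property
    def bases_3to5(self) -> str:
        """Probe sequence written 3'->5', i.e. aligned with the target 5'->3'."""
        return self.bases[::-1]

    @property
    def probe_id(self) -> str:
        if not self.mismatches:
            return "PM"
        tag = "_".join(f"{pos}{var}" for pos, var in self.mismatches)
        return f"{self.n_mismatch}MM_{tag}"

    def mismatch_positions(self) -> tuple[int, ...]:
        return tuple(pos for pos, _ in self.mismatches)

    def variant_at(self, position: int) -> str | None:
        for pos, var in self.mismatches:
            if pos == position:
                return var
        return None


def _build_probe(target: TargetSequence, mutations: Sequence[tuple[int, str]]) -> Probe:
    mutated = target.with_mutations(mutations)
    return Probe(bases=reverse_complement(mutated.bases), mismatches=tuple(sorted(mutations)))


@dataclass(frozen=True)
class MutationHypothesis:
    """A candidate point mutation of the target.

    ``position`` and ``alt_base`` are in target-strand coordinates.  ``label``
    is the printed nucleotide notation (possibly in an assay-specific counter
    frame, e.g. the KRAS panel counts positions in the opposite direction);
    ``aa_label`` optionally carries the amino-acid alias (e.g. ``G12A``).
    """

    position: int
    wt_base: str
    alt_base: str
    label: str
    aa_label: str | None = None

    def __post_init__(self) -> None:
        if self.alt_base == self.wt_base:
            raise InvalidSequenceError(f"hypothesis {self.label}: alt equals wild type")


_LABEL_RE = re.compile(rf"^(\d+)([ACGT])(?:{ARROW}|>)([ACGT])$")


def parse_label(label: str) -> tuple[int, str, str]:
    """Parse ``"10C→G"`` (or ``"10C>G"``) into ``(counter, wt, alt)``."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse mutation label {label!r}")
    return int(m.group(1)), m.group(2), m.group(3)


def format_label(counter: int, wt: str, alt: str) -> str:
    return f"{counter}{wt}{ARROW}{alt}"


@dataclass(frozen=True)
class Probeset:
    """The full PM/1MM/2MM probe family for one target."""

    target: TargetSequence
    probes: tuple[Probe, ...]
    edge_margin: int
    min_separation: int
    _by_position: dict[int, tuple[Probe, ...]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        index: dict[int, list[Probe]] = {}
        for probe in self.probes:
            for pos, _ in probe.mismatches:
                index.setdefault(pos, []).append(probe)
        object.__setattr__(
            self, "_by_position", {p: tuple(v) for p, v in index.items()}
        )

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def pm_probe(self) -> Probe:
        return next(p for p in self.probes if p.n_mismatch == 0)

    def eligible_positions(self) -> tuple[int, ...]:
        lo, hi = self.edge_margin + 1, len(self.target) - self.edge_margin
        return tuple(range(lo, hi + 1))

    def probes_at(self, position: int) -> tuple[Probe, ...]:
        """All probes carrying a mismatch at a target position."""
        return self._by_position.get(position, ())

    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p.probe_id for p in self.probes)


def design_probeset(
    target: TargetSequence, edge_margin: int = 4, min_separation: int = 5
) -> Probeset:
    """Enumerate the PM probe plus every admissible 1MM and 2MM probe.

    Mismatch positions are restricted to the interior of the duplex
    (``edge_margin`` bases excluded at each end) and, for double mismatches,
    to pairs at least ``min_separation`` nt apart, so that free-energy
    penalties stay additive (no mismatch-mismatch or mismatch-edge
    interaction).

    Returns probes in a deterministic order: PM, then 1MM sorted by
    (position, variant base), then 2MM sorted by (pos1, pos2, var1, var2).
    """
    if edge_margin < 1:
        raise ProbesetDesignError("edge_margin must be >= 1")
    if min_separation < 2:
        raise ProbesetDesignError("min_separation must be >= 2")
    lo, hi = edge_margin + 1, len(target) - edge_margin
    positions = list(range(lo, hi + 1))
    if not positions:
        raise ProbesetDesignError(
            f"target {target.name!r} ({len(target)} nt) admits no interior mismatch "
            f"position with edge_margin={edge_margin}"
        )

    probes: list[Probe] = [_build_probe(target, ())]
    for pos in positions:
        wt = target.base_at(pos)
        for var in sorted(DNA_ALPHABET - {wt}):
            probes.append(_build_probe(target, [(pos, var)]))
    for i in positions:
        wt_i = target.base_at(i)
        for j in positions:
            if j - i < min_separation:
                continue
            wt_j = target.base_at(j)
            for var_i in sorted(DNA_ALPHABET - {wt_i}):
                for var_j in sorted(DNA_ALPHABET - {wt_j}):
                    probes.append(_build_probe(target, [(i, var_i), (j, var_j)]))

    unique = {p.probe_id: p for p in probes}
    if len(unique) != len(probes):  # cannot happen for a valid alphabet; guard anyway
        probes = list(unique.values())
    return Probeset(
        target=target,
        probes=tuple(probes),
        edge_margin=edge_margin,
        min_separation=min_separation,
    )


def enumerate_hypotheses(
    target: TargetSequence,
    positions: Sequence[int],
    counter_map: Callable[[int], int] | None = None,
    aa_aliases: Mapping[str, str] | None = None,
) -> list[MutationHypothesis]:
    """All three substitution hypotheses at each given target position.

    ``counter_map`` converts a target coordinate into the printed position
    counter used in labels (identity when omitted); ``aa_aliases`` maps
    nucleotide labels to amino-acid notation.
    """
    hypotheses: list[MutationHypothesis] = []
    for pos in sorted(set(positions)):
        wt = target.base_at(pos)  # raises IndexError if outside the target
        counter = counter_map(pos) if counter_map else pos
        for alt in sorted(DNA_ALPHABET - {wt}):
            label = format_label(counter, wt, alt)
            hypotheses.append(
                MutationHypothesis(
                    position=pos,
                    wt_base=wt,
                    alt_base=alt,
                    label=label,
                    aa_label=(aa_aliases or {}).get(label),
                )
            )
    return hypotheses


def probes_for_hypothesis(
    probeset: Probeset, hypothesis: MutationHypothesis
) -> tuple[list[Probe], list[Probe]]:
    """Split the probes mismatched at the hypothesis position.

    Returns ``(mutation_set, side_set)``: probes whose variant at the position
    equals the hypothesis' alternative base (these pair the mutant perfectly
    there and form the mutation branch), and probes varying at the same
    position with a different base (side branch).  The sets are disjoint and
    together exhaust the probes mismatched at that position.
    """
    at_pos = probeset.probes_at(hypothesis.position)
    if not at_pos:
        raise UncoveredPositionError(
            f"position {hypothesis.position} is not covered by any probe "
            f"(eligible: {probeset.eligible_positions()[0]}.."
            f"{probeset.eligible_positions()[-1]})"
        )
    mutation_set = [p for p in at_pos if p.variant_at(hypothesis.position) == hypothesis.alt_base]
    side_set = [p for p in at_pos if p.variant_at(hypothesis.position) != hypothesis.alt_base]
    return mutation_set, side_set


# ---------------------------------------------------------------------------
# serialization: FASTA for probe sequences, TSV sidecar for annotations


def write_probeset_fasta(probeset: Probeset, path: str | Path) -> None:
    """Write probes as FASTA (5'->3'); headers encode mismatches as pos:wt>alt."""
    records = [
        SeqRecord(
            Seq(probeset.target.bases),
            id=f"target|{probeset.target.name}",
            description=f"edge_margin={probeset.edge_margin} min_separation={probeset.min_separation}",
        )
    ]
    for probe in probeset.probes:
        tokens = ";".join(
            f"{pos}:{probeset.target.base_at(pos)}>{var}" for pos, var in probe.mismatches
        )
        records.append(
            SeqRecord(Seq(probe.bases), id=probe.probe_id, description=tokens or "PM")
        )
    SeqIO.write(records, str(path), "fasta")


def read_probeset_fasta(path: str | Path) -> Probeset:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records or not records[0].id.startswith("target|"):
        raise ProbesetDesignError(f"{path}: first FASTA record must be the target")
    header = records[0]
    params = dict(
        token.split("=") for token in header.description.split() if "=" in token
    )
    target = TargetSequence(str(header.seq), name=header.id.split("|", 1)[1])
    probes = []
    for rec in records[1:]:
        mismatches = []
        desc = rec.description.removeprefix(rec.id).strip()
        if desc and desc != "PM":
            for token in desc.split(";"):
                pos_part, change = token.split(":")
                _, alt = change.split(">")
                mismatches.append((int(pos_part), alt))
        probes.append(Probe(bases=str(rec.seq), mismatches=tuple(sorted(mismatches))))
    return Probeset(
        target=target,
        probes=tuple(probes),
        edge_margin=int(params.get("edge_margin", 1)),
        min_separation=int(params.get("min_separation", 2)),
    )


def probeset_to_frame(probeset: Probeset) -> pd.DataFrame:
    rows = [
        {
            "probe_id": p.probe_id,
            "n_mismatch": p.n_mismatch,
            "positions": ",".join(str(pos) for pos, _ in p.mismatches),
            "variant_bases": ",".join(var for _, var in p.mismatches),
            "bases": p.bases,
        }
        for p in probeset.probes
    ]
    return pd.DataFrame(rows)


def write_probeset_tsv(probeset: Probeset, path: str | Path) -> None:
    probeset_to_frame(probeset).to_csv(path, sep="\t", index=False)
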