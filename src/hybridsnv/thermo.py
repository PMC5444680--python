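"""Duplex free-energy model.

Spot intensity in the linear Langmuir regime is I = A * c * exp(-dG/RT), so
all sequence information enters through the probe-target free energy dG.  We
use a first-order additive model: dG equals a perfect-match baseline plus one
penalty ddG >= 0 for every non-Watson-Crick pairing in the duplex.  To this
order the penalty depends only on the mismatch context (which target base
faces which probe base), not on its position, which is what makes the branch
distance rho a single number per mutation.

The package never needs literature penalty values for inference (the
concentration profile estimates exp(-ddG/RT) from data); the default table
below drives the simulator and examples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .probeset import (
    DNA_ALPHABET,
    HybridSNVError,
    Probe,
    TargetSequence,
    complement_base,
)


class MissingPenaltyError(HybridSNVError):
    pass


class LengthMismatchError(HybridSNVError):
    pass


@dataclass(frozen=True)
class ThermoConfig:
    """Temperature scale of the experiment.

    Defaults to the 65 degC hybridization-oven temperature; R in
    kcal/(mol*K) so that RT is in kcal/mol (~0.672 at 65 degC).
    """

    temperature: float = 338.15
    gas_constant: float = 1.987e-3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


def _context_key(target_base: str, probe_base: str) -> str:
    return f"{target_base}/{probe_base}"


# Defaults for the simulator, kcal/mol at 65 degC.  The three C/x contexts are
# the panel-relevant mismatches (wild-type C on the target strand opposite a
# non-G probe base); their magnitudes are anchored to measured concentration
# -profile slopes for this assay (exp(ddG/RT) between ~81 and ~649).  The
# remaining contexts follow the qualitative nearest-neighbor stability
# ordering, with the G.T wobble cheapest.
DEFAULT_PENALTIES: Mapping[str, float] = {
    "G/T": 1.40,
    "T/G": 1.50,
    "G/G": 1.70,
    "G/A": 1.80,
    "A/G": 1.90,
    "A/A": 2.10,
    "T/T": 2.20,
    "A/C": 2.40,
    "T/C": 2.50,
    "C/T": 2.95,
    "C/A": 3.70,
    "C/C": 4.35,
}


@dataclass(frozen=True)
class PenaltyTable:
    """Mismatch free-energy penalties ddG = dG(mismatch) - dG(match) >= 0.

    Keyed by context ``"X/Y"``: target base X opposite probe base Y (Y is not
    the Watson-Crick complement of X).  Optional position-specific overrides
    use keys ``"X/Y@pos"`` (1-based target coordinate); the position-free
    entry remains the fallback, matching the first-order assumption that the
    penalty is position independent.
    """

    entries: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PENALTIES))

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            if value < 0:
                raise ValueError(f"penalty {key} = {value} < 0; a mismatch never strengthens the duplex")

    @classmethod
    def default(cls) -> "PenaltyTable":
        return cls()

    @classmethod
    def uniform(cls, value: float) -> "PenaltyTable":
        keys = [
            _context_key(t, p)
            for t in sorted(DNA_ALPHABET)
            for p in sorted(DNA_ALPHABET)
            if p != complement_base(t)
        ]
        return cls({k: float(value) for k in keys})

    def lookup(self, target_base: str, probe_base: str, position: int | None = None) -> float:
        if probe_base == complement_base(target_base):
            return 0.0  # Watson-Crick pair carries no penalty
        key = _context_key(target_base, probe_base)
        if position is not None and f"{key}@{position}" in self.entries:
            return self.entries[f"{key}@{position}"]
        try:
            return self.entries[key]
        except KeyError:
            raise MissingPenaltyError(
                f"no penalty for mismatch context {key} (target {target_base} vs probe {probe_base})"
            ) from None

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            sorted(self.entries.items()), columns=["context", "ddg_kcal_per_mol"]
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PenaltyTable":
        frame = pd.read_csv(path, sep="\t")
        missing = {"context", "ddg_kcal_per_mol"} - set(frame.columns)
        if missing:
            raise HybridSNVError(f"{path}: missing columns {sorted(missing)}")
        return cls(dict(zip(frame["context"], frame["ddg_kcal_per_mol"].astype(float))))


def duplex_delta_g(
    probe: Probe,
    target: TargetSequence,
    dg_pm: float = 0.0,
    penalties: PenaltyTable | None = None,
) -> float:
    """Free energy of one probe-target duplex under the additive model.

    Returns ``dg_pm`` plus one penalty for every position where the probe base
    does not Watson-Crick pair the target base.  The target may be any species
    (wild type or mutant) of the probe's length.
    """
    if len(probe.bases) != len(target):
        raise LengthMismatchError(
            f"probe {probe.probe_id} is {len(probe.bases)} nt but target "
            f"{target.name!r} is {len(target)} nt"
        )
    penalties = penalties or PenaltyTable.default()
    aligned = probe.bases_3to5  # probe read 3'->5' pairs the target 5'->3'
    dg = dg_pm
    for i, (t_base, p_base) in enumerate(zip(target.bases, aligned), start=1):
        dg += penalties.lookup(t_base, p_base, position=i)
    return dg


def delta_delta_g(
    probe: Probe,
    wild_type: TargetSequence,
    mutant: TargetSequence,
    penalties: PenaltyTable | None = None,
) -> float:
    """ddG = dG(probe, mutant) - dG(probe, wild type).

    Negative for mutation-branch probes (the probe binds the mutant better),
    positive for the PM probe, and equal across all probes of one mutation
    branch under the position-independent additive model.
    """
    return duplex_delta_g(probe, mutant, 0.0, penalties) - duplex_delta_g(
        probe, wild_type, 0.0, penalties
    )
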