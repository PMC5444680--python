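"""Synthetic microarray generator for the competitive hybridization model.

Expected spot intensity follows the linear Langmuir isotherm

    I = A * sum_s  c_s * exp(-dG(probe, s) / RT)

summed over the target species s in solution (a pure sample reduces to the
single-species law).  The measurement process emulates the platform: each
probe is spotted in ``n_replicates`` identical spots, every replicate draws
multiplicative lognormal noise (median one) plus an additive optical
background, the per-probe signal is the median over replicates, the vendor
pipeline's mean-background subtraction is applied, and signals below an
intensity floor are flagged.

All randomness comes from ``numpy.random.default_rng`` (PCG64), so a table is
fully reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .probeset import HybridSNVError, MutationHypothesis, Probe, Probeset, TargetSequence
from .thermo import PenaltyTable, ThermoConfig, duplex_delta_g


@dataclass(frozen=True)
class SampleSpec:
    """Composition of one hybridization sample.

    ``species`` holds ``(target sequence, concentration in nM)`` pairs; by
    convention the first species is the wild type.
    """

    species: tuple[tuple[TargetSequence, float], ...]

    def __post_init__(self) -> None:
        if not self.species:
            raise HybridSNVError("sample must contain at least one species")
        if any(c < 0 for _, c in self.species):
            raise HybridSNVError("concentrations must be >= 0")

    @classmethod
    def pure(cls, target: TargetSequence, c_total: float) -> "SampleSpec":
        return cls(((target, float(c_total)),))

    @classmethod
    def mixture(
        cls,
        wild_type: TargetSequence,
        mutant: TargetSequence,
        c_total: float,
        mutant_fraction: float,
    ) -> "SampleSpec":
        """Two-species mixture; ``mutant_fraction`` is c_mut / c_total."""
        if not 0 <= mutant_fraction <= 1:
            raise HybridSNVError("mutant_fraction must be in [0, 1]")
        c_mut = c_total * mutant_fraction
        return cls(((wild_type, c_total - c_mut), (mutant, c_mut)))

    @property
    def c_total(self) -> float:
        return sum(c for _, c in self.species)

    @property
    def mutant_fraction(self) -> float:
        """c_mut / c_total, counting everything beyond the first species as mutant."""
        total = self.c_total
        return sum(c for _, c in self.species[1:]) / total if total else 0.0

    def describe(self) -> str:
        return " + ".join(f"{t.name}:{c:g}nM" for t, c in self.species)


@dataclass(frozen=True)
class SimulationConfig:
    """Device and noise parameters of the simulated array.

    ``a`` is the optical proportionality factor (fluorescence units per nM);
    ``dg_pm`` the perfect-match duplex free energy baseline (kcal/mol; it only
    shifts the overall scale, which ``a`` absorbs); ``noise_cv`` the
    coefficient of variation of the multiplicative lognormal spot noise;
    background is additive Gaussian per replicate (clipped at zero) in
    intensity units.  ``subtract_background`` applies the platform's mean
    -background subtraction to the reported signal.  ``saturating`` switches
    to the full isotherm I = A z / (1 + z); the default is the linear regime
    the analysis assumes.
    """

    a: float = 10_000.0
    dg_pm: float = 0.0
    penalties: PenaltyTable = field(default_factory=PenaltyTable.default)
    thermo: ThermoConfig = field(default_factory=ThermoConfig)
    n_replicates: int = 8
    noise_cv: float = 0.15
    background_mean: float = 2.0
    background_sd: float = 0.6
    background_threshold: float | None = None  # default: 2 * background_mean
    subtract_background: bool = True
    saturating: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise HybridSNVError("optical factor a must be positive")
        if self.n_replicates < 1:
            raise HybridSNVError("need at least one replicate spot")
        if min(self.noise_cv, self.background_mean, self.background_sd) < 0:
            raise HybridSNVError("noise parameters must be >= 0")

    @property
    def threshold(self) -> float:
        if self.background_threshold is not None:
            return self.background_threshold
        return 2.0 * self.background_mean


@dataclass
class IntensityTable:
    """Per-probe aggregated intensities for one hybridization.

    ``data`` columns: probe_id, intensity, n_replicates, below_background.
    ``meta`` records the sample composition and seed for provenance.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"probe_id", "intensity", "n_replicates", "below_background"}
        missing = required - set(self.data.columns)
        if missing:
            raise HybridSNVError(f"intensity table missing columns {sorted(missing)}")
        if (self.data["intensity"] < 0).any():
            raise HybridSNVError("intensities must be >= 0")
        if self.data["probe_id"].duplicated().any():
            dup = self.data.loc[self.data["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise HybridSNVError(f"duplicate probe_id {dup!r}")

    def __len__(self) -> int:
        return len(self.data)

    def scaled(self, factor: float) -> "IntensityTable":
        """Same array read out with the optical gain multiplied by ``factor``."""
        data = self.data.copy()
        data["intensity"] = data["intensity"] * factor
        meta = dict(self.meta, scale_factor=self.meta.get("scale_factor", 1.0) * factor)
        return IntensityTable(data=data, meta=meta)


def expected_intensity(
    probe: Probe, sample: SampleSpec, config: SimulationConfig
) -> float:
    """Noise-free competitive Langmuir intensity of one probe."""
    rt = config.thermo.rt
    z = 0.0
    for target, conc in sample.species:
        dg = duplex_delta_g(probe, target, config.dg_pm, config.penalties)
        z += conc * math.exp(-dg / rt)
    if config.saturating:
        return config.a * z / (1.0 + z)
    return config.a * z


def simulate_array(
    probeset: Probeset,
    sample: SampleSpec,
    config: SimulationConfig,
    seed: int | None = None,
) -> IntensityTable:
    """Simulate one hybridization of ``sample`` against the probeset.

    Per probe: ``n_replicates`` draws of expected * LogNormal(0, sigma) plus
    clipped-Gaussian background, aggregated by the replicate median; the mean
    background is subtracted (if configured) and the result floored at zero.
    Rows whose signal falls below the background threshold are flagged, not
    removed — filtering belongs to the scatter construction downstream.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(config.noise_cv**2))
    rows = []
    for probe in probeset.probes:
        mu = expected_intensity(probe, sample, config)
        reps = mu * rng.lognormal(mean=0.0, sigma=sigma, size=config.n_replicates)
        if config.background_mean > 0 or config.background_sd > 0:
            bg = rng.normal(config.background_mean, config.background_sd, config.n_replicates)
            reps = reps + np.clip(bg, 0.0, None)
        signal = float(np.median(reps))
        if config.subtract_background:
            signal = max(signal - config.background_mean, 0.0)
        rows.append(
            {
                "probe_id": probe.probe_id,
                "intensity": signal,
                "n_replicates": config.n_replicates,
                "below_background": signal < config.threshold,
            }
        )
    meta = {
        "sample": sample.describe(),
        "c_total_nM": sample.c_total,
        "mutant_fraction": sample.mutant_fraction,
        "seed": seed,
        "rng": "PCG64",
        "n_probes": len(probeset),
    }
    return IntensityTable(data=pd.DataFrame(rows), meta=meta)


def dilution_fractions(
    start_fraction: float, dilution_factor: float, n_steps: int
) -> list[float]:
    """Mutant fractions c_mut/c_total of a geometric dilution series."""
    if not 0 < start_fraction <= 1:
        raise HybridSNVError("start_fraction must be in (0, 1]")
    if dilution_factor <= 1:
        raise HybridSNVError("dilution_factor must exceed 1")
    return [start_fraction / dilution_factor**k for k in range(n_steps)]


def make_dilution_series(
    probeset: Probeset,
    mutation: MutationHypothesis,
    start_fraction: float,
    dilution_factor: float,
    n_steps: int,
    config: SimulationConfig,
    c_total: float = 5.0,
    seed: int | None = None,
) -> tuple[IntensityTable, list[tuple[SampleSpec, IntensityTable]]]:
    """A geometric dilution series of one mutant, plus a pure wild-type reference.

    Fractions are ``start_fraction / dilution_factor**k`` (c_mut/c_total) at a
    constant total concentration.  Returns ``(reference_table, [(sample,
    table), ...])`` ordered from the highest fraction down.
    """
    if seed is None:
        seed = config.seed
    seeder = np.random.default_rng(seed)
    child = lambda: int(seeder.integers(2**31))  # noqa: E731

    wild_type = probeset.target
    mutant = wild_type.with_mutations([(mutation.position, mutation.alt_base)])
    reference = simulate_array(
        probeset, SampleSpec.pure(wild_type, c_total), config, seed=child()
    )
    series = []
    for fraction in dilution_fractions(start_fraction, dilution_factor, n_steps):
        sample = SampleSpec.mixture(wild_type, mutant, c_total, fraction)
        series.append((sample, simulate_array(probeset, sample, config, seed=child())))
    return reference, series


NOISE_FREE = dict(noise_cv=0.0, background_mean=0.0, background_sd=0.0, background_threshold=0.0)


def noise_free(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A copy of ``config`` with all noise and background switched off."""
    base = config or SimulationConfig()
    return replace(base, **{**NOISE_FREE, **overrides})
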