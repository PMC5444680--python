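"""Intensity-table format, run configuration, fixtures and pipeline glue.

The package defines a single platform-free TSV dialect for per-probe
intensities (columns probe_id, intensity, n_replicates, below_background;
``#``-prefixed ``key=value`` header lines carry sample metadata).  Vendor
exports are mapped into this dialect by the user — only probe identity and a
background-filtered intensity are needed, which any feature-extraction output
provides.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import kras
from .branchfit import ReferenceLine, ScatterData, build_scatter, fit_reference_line
from .detect import SampleCall, call_sample
from .probeset import HybridSNVError, MutationHypothesis, Probeset
from .simulate import IntensityTable, SampleSpec, SimulationConfig, simulate_array

REQUIRED_COLUMNS = ("probe_id", "intensity", "n_replicates", "below_background")


class TableFormatError(HybridSNVError):
    pass


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for key, value in table.meta.items():
            fh.write(f"# {key}={value}\n")
        table.data.to_csv(fh, sep="\t", index=False)


def load_intensity_table(path: str | Path) -> IntensityTable:
    """Read and validate an intensity TSV; errors carry 1-based line numbers."""
    path = Path(path)
    meta: dict[str, Any] = {}
    header_lines = 0
    with open(path, newline="") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()

    try:
        frame = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # malformed beyond recovery
        raise TableFormatError(f"{path}: cannot parse TSV ({exc})") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")

    numeric = pd.to_numeric(frame["intensity"], errors="coerce")
    bad = frame.index[numeric.isna()]
    if len(bad):
        line_no = int(bad[0]) + header_lines + 2  # +1 header row, +1 one-based
        raise TableFormatError(
            f"{path}: non-numeric intensity {frame.loc[bad[0], 'intensity']!r} on line {line_no}"
        )
    frame["intensity"] = numeric.astype(float)

    dup = frame["probe_id"][frame["probe_id"].duplicated()]
    if len(dup):
        first = dup.iloc[0]
        line_no = int(dup.index[0]) + header_lines + 2
        raise TableFormatError(f"{path}: duplicate probe_id {first!r} (line {line_no})")

    if frame["below_background"].dtype == object:
        frame["below_background"] = frame["below_background"].astype(str).str.lower().isin(
            ["true", "1", "yes"]
        )
    frame["below_background"] = frame["below_background"].astype(bool)
    frame["n_replicates"] = frame["n_replicates"].astype(int)
    return IntensityTable(data=frame[list(REQUIRED_COLUMNS)], meta=meta)


def write_call_report(call: SampleCall, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(call.as_dict(), fh, indent=2)
        fh.write("\n")


def call_to_frame(call: SampleCall) -> pd.DataFrame:
    """Per-hypothesis summary table (mirrors the supplementary-table layout)."""
    return pd.DataFrame([r.as_dict() for r in call.results])


def analyze_pair(
    reference: IntensityTable,
    test: IntensityTable,
    probeset: Probeset,
    hypotheses: list[MutationHypothesis],
    background_threshold: float | None = None,
    span: float = 0.5,
    n_robust_iter: int = 3,
    alpha: float = 0.01,
) -> tuple[ScatterData, ReferenceLine, SampleCall]:
    """Full analysis of one test sample against its wild-type reference."""
    scatter = build_scatter(reference, test, background_threshold=background_threshold)
    line = fit_reference_line(scatter, span=span, n_robust_iter=n_robust_iter)
    call = call_sample(scatter, line, probeset, hypotheses, alpha=alpha)
    return scatter, line, call


# ---------------------------------------------------------------------------
# run configuration


DEFAULT_PARAMS = {
    "edge_margin": 4,
    "min_separation": 5,
    "span": 0.5,
    "n_robust_iter": 3,
    "alpha": 0.01,
    "rho_t": 0.5,
    "background_threshold": None,
}


def load_run_config(path: str | Path) -> dict[str, Any]:
    """YAML run configuration merged over the documented defaults."""
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise HybridSNVError(f"{path}: config must be a YAML mapping")
    config = dict(DEFAULT_PARAMS)
    config.update(loaded)
    for key in ("probeset", "penalties", "reference", "test"):
        if key in config and config[key] and not Path(config[key]).exists():
            raise HybridSNVError(f"{path}: referenced file {config[key]!r} does not exist")
    return config


# ---------------------------------------------------------------------------
# fixture generation: synthetic analogues of the three experiment sets


def make_fixtures(
    outdir: str | Path,
    seed: int,
    probeset: Probeset | None = None,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Generate the three synthetic experiment sets and a ground-truth manifest.

    Set 1: geometric dilution series of 10C→G (start 10%, factor 2.5, six
    steps) at 5 nM total.  Set 2: the 12 panel mutants each at 5% plus a pure
    wild-type negative control, at 10 nM.  Set 3: seven clinical-like samples
    (elevated noise, unknown fractions drawn from 5-40%, random panel
    mutations) at 10 nM.  Each set gets its own wild-type reference array.

    Writes one TSV per hybridization plus ``manifest.tsv`` and returns the
    manifest frame (columns: sample_id, experiment_set, path, reference_path,
    true_mutation, fraction_total, c_total_nM, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probeset = probeset or kras.default_probeset()
    config = config or SimulationConfig()
    panel = kras.kras_panel()
    wild_type = probeset.target

    seeder = np.random.default_rng(seed)
    child = lambda: int(seeder.integers(2**31))  # noqa: E731
    rows: list[dict[str, Any]] = []

    def emit(name, set_name, sample, sim_config, reference_path, mutation, fraction):
        table_seed = child()
        table = simulate_array(probeset, sample, sim_config, seed=table_seed)
        path = outdir / f"{name}.tsv"
        write_intensity_table(table, path)
        rows.append(
            {
                "sample_id": name,
                "experiment_set": set_name,
                "path": path.name,
                "reference_path": reference_path,
                "true_mutation": mutation,
                "fraction_total": fraction,
                "c_total_nM": sample.c_total,
                "seed": table_seed,
            }
        )

    # --- set 1: dilution series of 10C→G at 5 nM total
    dilution_mutation = kras.kras_hypothesis("10C→G")
    mutant = wild_type.with_mutations(
        [(dilution_mutation.position, dilution_mutation.alt_base)]
    )
    emit("set1_ref", "set1", SampleSpec.pure(wild_type, 5.0), config, "", "wild type", 0.0)
    fraction = 0.10
    for step in range(6):
        emit(
            f"set1_dilution{step}",
            "set1",
            SampleSpec.mixture(wild_type, mutant, 5.0, fraction),
            config,
            "set1_ref.tsv",
            dilution_mutation.label,
            fraction,
        )
        fraction /= 2.5

    # --- set 2: the 12 panel mutants at 5% plus wild-type control, 10 nM
    emit("set2_ref", "set2", SampleSpec.pure(wild_type, 10.0), config, "", "wild type", 0.0)
    for h in panel:
        mut = wild_type.with_mutations([(h.position, h.alt_base)])
        emit(
            f"set2_{h.aa_label or h.label}",
            "set2",
            SampleSpec.mixture(wild_type, mut, 10.0, 0.05),
            config,
            "set2_ref.tsv",
            h.label,
            0.05,
        )
    emit(
        "set2_wt_control",
        "set2",
        SampleSpec.pure(wild_type, 10.0),
        config,
        "set2_ref.tsv",
        "wild type",
        0.0,
    )

    # --- set 3: clinical-like samples, degraded-material noise, blind fractions
    from dataclasses import replace

    clinical_config = replace(config, noise_cv=max(config.noise_cv, 0.30))
    emit("set3_ref", "set3", SampleSpec.pure(wild_type, 10.0), config, "", "wild type", 0.0)
    picks = seeder.choice(len(panel), size=7, replace=True)
    fractions = seeder.uniform(0.05, 0.40, size=7)
    for k, (idx, frac) in enumerate(zip(picks, fractions), start=1):
        h = panel[int(idx)]
        mut = wild_type.with_mutations([(h.position, h.alt_base)])
        emit(
            f"set3_clinical{k}",
            "set3",
            SampleSpec.mixture(wild_type, mut, 10.0, float(frac)),
            clinical_config,
            "set3_ref.tsv",
            h.label,
            float(frac),
        )

    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
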