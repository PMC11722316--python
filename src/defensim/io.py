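"""Readers/writers for the package's TSV/YAML artifacts and the two
pipelines (simulation study, genomics study).

All tables are UTF-8 TSV with '.' decimals; lines starting with '#' are
comments.  Every pipeline run writes a JSON manifest recording the config,
seeds, inputs/outputs and per-stage wall-clock, so reruns with identical
inputs and seeds reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemostat import Environment, Strategy

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "read_table",
    "write_table",
    "load_environment",
    "save_environment",
    "RunManifest",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A table file does not match its declared schema."""


#: required columns (name -> pandas dtype kind: 'f' float, 'i' int, 's' str)
SCHEMAS: dict[str, dict[str, str]] = {
    "investment": {
        "species_id": "s", "genome_length": "f", "I_Imm": "f", "I_PCD": "f",
    },
    "annotation": {
        "genome_id": "s", "species_id": "s", "genome_length": "f",
        "gene_id": "s", "contig": "s", "start": "i", "end": "i",
        "strand": "s", "system_label": "s", "role": "s",
    },
    "classification": {"system_label": "s", "category": "s"},
    "rank_abundance": {"species": "s", "sample": "s", "rank": "i"},
    "landscape": {"a": "f", "r": "f", "r_over_E": "f", "fitness": "f"},
    "sweep": {
        "param_value": "f", "a_opt": "f", "r_opt": "f", "r_opt_over_E": "f",
        "fitness": "f", "sensitivity": "f",
    },
    "timeseries": {"t": "f", "total_cells": "f", "phi": "f", "psi": "f"},
    "state_matrix": {"p": "i", "q": "i", "count": "f"},
    "deviation": {
        "system": "s", "p_high": "f", "p_low": "f", "signed_log_p_high": "f",
        "signed_log_p_low": "f", "p_diff": "f", "quadrant": "s",
    },
}

_KIND_CAST = {"f": float, "i": "int64", "s": str}


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a TSV table against a named schema.

    Missing columns raise :class:`SchemaError` naming the column;
    unparseable numeric values raise with the offending line number.
    An empty file with a valid header yields an empty table.
    """
    schema = SCHEMAS[schema_name]
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} "
                          f"for schema '{schema_name}'")
    for col, kind in schema.items():
        if kind == "s":
            continue
        raw = frame[col].to_numpy(dtype=object)
        try:
            # numpy's parser round-trips float text exactly
            values = np.asarray(raw, dtype=np.float64)
        except (ValueError, TypeError):
            for row, text in enumerate(raw):
                try:
                    float(text)
                except (ValueError, TypeError):
                    raise SchemaError(
                        f"{path}: unparseable numeric in column '{col}' "
                        f"at line {row + 2}"
                    ) from None
            raise
        frame[col] = values.astype("int64") if kind == "i" else values
    return frame


def write_table(frame: pd.DataFrame, path, schema_name: str | None = None) -> None:
    """Write a table as canonical TSV (validating columns when a schema is
    named)."""
    if schema_name is not None:
        missing = [c for c in SCHEMAS[schema_name] if c not in frame.columns]
        if missing:
            raise SchemaError(f"cannot write '{schema_name}': missing {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def load_environment(path) -> tuple[Environment, Strategy | None]:
    """Load an Environment (and optional Strategy keys a/r) from YAML/JSON."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    env_fields = {f.name for f in fields(Environment)}
    unknown = set(raw) - env_fields - {"a", "r"}
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    env_kwargs = {k: v for k, v in raw.items() if k in env_fields}
    env = Environment(**env_kwargs)
    strat = None
    if "a" in raw or "r" in raw:
        strat = Strategy(a=float(raw.get("a", 0.0)), r=float(raw.get("r", 0.0)))
    return env, strat


def save_environment(env: Environment, path, strat: Strategy | None = None) -> None:
    data = asdict(env)
    if strat is not None:
        data.update(a=strat.a, r=strat.r)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    pipeline: str
    version: str = __version__
    config_hash: str = ""
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    wall_clock_s: float = 0.0

    def log_stage(self, name: str, seconds: float, **info) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **info})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _hash_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Execute a named pipeline end to end, persisting intermediates.

    ``config["pipeline"]`` selects ``"genomics-study"`` (investment table ->
    power-law fits + BIC -> abundance classes -> deviation analysis) or
    ``"simulate-study"`` (landscape / parameter sweep).  Stage failures
    propagate after being recorded in the manifest.
    """
    from . import abundance, landscape, powerlaw

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = config.get("pipeline")
    manifest = RunManifest(pipeline=str(name), config_hash=_hash_config(config),
                           seeds={"seed": config.get("seed", 0)},
                           inputs={k: str(v) for k, v in
                                   config.get("inputs", {}).items()})
    t0 = time.perf_counter()
    try:
        if name == "genomics-study":
            _run_genomics(config, out, manifest)
        elif name == "simulate-study":
            _run_simulation(config, out, manifest)
        else:
            raise ValueError(f"unknown pipeline {name!r}")
    except Exception as exc:
        manifest.log_stage("failed", time.perf_counter() - t0, error=str(exc))
        manifest.save(out / "manifest.json")
        raise
    manifest.wall_clock_s = round(time.perf_counter() - t0, 3)
    manifest.save(out / "manifest.json")
    return manifest


def _run_genomics(config: dict, out: Path, manifest: RunManifest) -> None:
    from . import abundance as ab
    from . import powerlaw as pl
    from .synth import SyntheticConfig, gen_investment_table, gen_rank_abundance

    seed = int(config.get("seed", 0))
    inputs = config.get("inputs", {})
    t0 = time.perf_counter()
    if "investment" in inputs:
        invest = read_table(inputs["investment"], "investment")
    else:
        synth_kwargs = dict(config.get("synthetic", {}))
        invest = gen_investment_table(SyntheticConfig(seed=seed, **synth_kwargs))
        write_table(invest, out / "investment.tsv", "investment")
    manifest.log_stage("investment", time.perf_counter() - t0, n=len(invest))

    t0 = time.perf_counter()
    model = pl.PowerLawInvestmentModel(invest)
    fits = [model.fit(), model.fit(fixed_alpha=1.0), model.fit(fixed_alpha=0.0)]
    fits[0].to_json(out / "fit.json")
    write_table(pl.bic_compare(fits), out / "bic.tsv")
    manifest.log_stage("powerlaw_fit", time.perf_counter() - t0,
                       alpha=fits[0].alpha)

    t0 = time.perf_counter()
    if "rank_abundance" in inputs:
        ranks = read_table(inputs["rank_abundance"], "rank_abundance")
    else:
        synth_kwargs = dict(config.get("synthetic_abundance", {}))
        ranks = gen_rank_abundance(SyntheticConfig(seed=seed, **synth_kwargs))
        write_table(ranks, out / "rank_abundance.tsv", "rank_abundance")
    min_samples = int(config.get("min_samples", 100))
    ta_range = config.get("Ta_range")
    genome_species = set(invest["species_id"])
    if ta_range is None:
        ta_max = int(ranks["rank"].max())
        ta_range = range(1, ta_max + 1)
    ta = ab.choose_threshold(ranks, genome_species, ta_range,
                             min_samples=min_samples)
    classes = ab.classify_abundance(ranks, ta, min_samples=min_samples)
    manifest.log_stage("abundance_classes", time.perf_counter() - t0,
                       Ta=ta, n_high=len(classes.high), n_low=len(classes.low))

    t0 = time.perf_counter()
    inv = invest.set_index("species_id")
    high = inv.reindex(classes.high).dropna(subset=["I_PCD"])
    low = inv.reindex(classes.low).dropna(subset=["I_PCD"])
    rows = []
    if not high.empty and not low.empty:
        posterior = ab.InvestmentSizeRegression(
            inv["I_PCD"], inv["genome_length"]
        ).fit(ab.MCMCConfig(seed=seed))
        for system, col in (("PCD", "I_PCD"), ("Immunity", "I_Imm")):
            post = posterior if col == "I_PCD" else ab.InvestmentSizeRegression(
                inv[col], inv["genome_length"]).fit(ab.MCMCConfig(seed=seed))
            dev = ab.deviation_pvalues(
                post, high["genome_length"], low["genome_length"],
                high[col].mean(), low[col].mean(),
                n_ensembles=int(config.get("n_ensembles", 10_000)), seed=seed,
            )
            rows.append({
                "system": system, "p_high": dev.p_high, "p_low": dev.p_low,
                "signed_log_p_high": dev.signed_log_p_high,
                "signed_log_p_low": dev.signed_log_p_low,
                "p_diff": dev.p_diff, "quadrant": dev.quadrant,
            })
        write_table(pd.DataFrame(rows), out / "deviation.tsv", "deviation")
    manifest.log_stage("deviation", time.perf_counter() - t0, n_systems=len(rows))
    manifest.outputs = {p.name: str(p) for p in sorted(out.glob("*"))}


def _run_simulation(config: dict, out: Path, manifest: RunManifest) -> None:
    import numpy as np

    from . import landscape as ls

    env, _ = (load_environment(config["inputs"]["config"])
              if "config" in config.get("inputs", {})
              else (Environment(**config.get("environment", {})), None))
    t0 = time.perf_counter()
    sweep_cfg = config.get("sweep")
    run_kwargs = dict(config.get("run_kwargs", {}))
    na = int(config.get("na", 21))
    nr = int(config.get("nr", 21))
    if sweep_cfg:
        res = ls.sweep_parameter(
            env, sweep_cfg["param"], np.asarray(sweep_cfg["values"], float),
            a_grid=None if na else None, **run_kwargs,
        )
        write_table(res.to_frame(), out / "sweep.tsv", "sweep")
        manifest.log_stage("sweep", time.perf_counter() - t0,
                           param=sweep_cfg["param"], n=len(res.values))
    else:
        land = ls.evaluate_landscape(
            env, ls.default_a_grid(env, na), ls.default_r_grid(env, nr),
            **run_kwargs,
        )
        write_table(land.to_frame(), out / "landscape.tsv", "landscape")
        manifest.log_stage("landscape", time.perf_counter() - t0,
                           a_opt=land.a_opt, r_opt=land.r_opt)
    manifest.outputs = {p.name: str(p) for p in sorted(out.glob("*"))}
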