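"""Parameter sweeps over transition scenarios.

A sweep samples (s_Y, s_new, epsilon) independently and uniformly per
replicate (default range (0, 0.05), with sM = -sF enforced at each SA
locus), runs the deterministic transition for each draw, and collects one
tidy row per replicate.  Replicate sub-streams are spawned from the master
seed by replicate index (``SeedSequence(master_seed, spawn_key=(i,))``), so
the output table is a pure function of the configuration and independent of
execution order and worker count.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recursion import RecombinationRates
from .scenarios import ScenarioSpec, run_transition

logger = logging.getLogger(__name__)

#: column order of the sweep results table
RESULT_COLUMNS = (
    "transition",
    "epi_type",
    "epi_partner",
    "replicate",
    "sub_seed",
    "s_Y",
    "s_new",
    "epsilon",
    "outcome_bit",
    "read_frequency",
    "p_Y",
    "p_A",
    "p_W",
    "p_SAY",
    "p_SAA",
    "p_SAW",
    "p_EPI",
    "generations_run",
    "error",
)

PROFILES = {"paper": (10_000, 200_000), "desk": (2_000, 20_000)}


@dataclass(frozen=True)
class SweepConfig:
    """Scenario template, sampling ranges and replication settings."""

    transition: str = "Y_to_A"
    epi_type: str = "dominance"
    epi_partner: str = "SAY"
    n_replicates: int = 1000
    s_Y_range: tuple = (0.0, 0.05)
    s_new_range: tuple = (0.0, 0.05)
    epsilon_range: tuple = (0.0, 0.05)
    master_seed: int = 0
    burn_in: int = 10_000
    total_generations: int = 200_000
    intro_freq: float = 1e-4
    rates: RecombinationRates = field(default_factory=RecombinationRates)
    read_mode: str = "within_sex"

    def __post_init__(self):
        for name in ("s_Y_range", "s_new_range", "epsilon_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi, got ({lo}, {hi})")
        if self.n_replicates < 0:
            raise ValueError("n_replicates must be >= 0")
        # template validation (partner/transition compatibility etc.)
        self.scenario(0.01, 0.01, 0.0)

    def with_profile(self, profile: str) -> "SweepConfig":
        burn_in, total = PROFILES[profile]
        return replace(self, burn_in=burn_in, total_generations=total)

    def scenario(self, s_Y: float, s_new: float, epsilon: float) -> ScenarioSpec:
        return ScenarioSpec(
            transition=self.transition,
            epi_type=self.epi_type,
            epi_partner=self.epi_partner,
            s_Y=s_Y,
            s_new=s_new,
            epsilon=epsilon,
            burn_in=self.burn_in,
            total_generations=self.total_generations,
            intro_freq=self.intro_freq,
            rates=self.rates,
            read_mode=self.read_mode,
        )

    def to_dict(self) -> dict:
        d = self.scenario(0.01, 0.01, 0.0).to_dict()
        for k in ("s_Y", "s_new", "epsilon"):
            d.pop(k)
        d.update(
            n_replicates=self.n_replicates,
            s_Y_range=list(self.s_Y_range),
            s_new_range=list(self.s_new_range),
            epsilon_range=list(self.epsilon_range),
            master_seed=self.master_seed,
        )
        return d


def _sub_seed(master_seed: int, replicate_index: int) -> int:
    seq = np.random.SeedSequence(master_seed, spawn_key=(replicate_index,))
    return int(seq.generate_state(1, dtype=np.uint32)[0])


def _draw_open(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Uniform draw strictly inside (lo, hi); a degenerate range returns lo."""
    if lo == hi:
        return lo
    while True:
        x = float(rng.uniform(lo, hi))
        if lo < x < hi:
            return x


def sample_parameters(config: SweepConfig, replicate_index: int):
    """(s_Y, s_new, epsilon) for one replicate; deterministic in (seed, index)."""
    seq = np.random.SeedSequence(config.master_seed, spawn_key=(replicate_index,))
    rng = np.random.default_rng(seq)
    s_Y = _draw_open(rng, *config.s_Y_range)
    s_new = _draw_open(rng, *config.s_new_range)
    epsilon = _draw_open(rng, *config.epsilon_range)
    return s_Y, s_new, epsilon


def _run_one(config: SweepConfig, i: int) -> dict:
    s_Y, s_new, epsilon = sample_parameters(config, i)
    row = {
        "transition": config.transition,
        "epi_type": config.epi_type,
        "epi_partner": config.epi_partner,
        "replicate": i,
        "sub_seed": _sub_seed(config.master_seed, i),
        "s_Y": s_Y,
        "s_new": s_new,
        "epsilon": epsilon,
        "outcome_bit": -1,
        "read_frequency": np.nan,
        "p_Y": np.nan,
        "p_A": np.nan,
        "p_W": np.nan,
        "p_SAY": np.nan,
        "p_SAA": np.nan,
        "p_SAW": np.nan,
        "p_EPI": np.nan,
        "generations_run": 0,
        "error": "",
    }
    try:
        outcome = run_transition(config.scenario(s_Y, s_new, epsilon))
    except Exception as exc:  # individual failures recorded, sweep continues
        logger.warning("replicate %d failed: %s", i, exc)
        row["error"] = f"{type(exc).__name__}: {exc}"
        return row
    row.update(outcome.final_freqs)
    row["outcome_bit"] = outcome.outcome_bit
    row["read_frequency"] = outcome.read_frequency
    row["generations_run"] = outcome.generations_run
    return row


def run_sweep(config: SweepConfig, jobs: int = 1, progress: bool = False) -> pd.DataFrame:
    """Run all replicates; returns one row per replicate in replicate order."""
    indices = range(config.n_replicates)
    if progress:
        logger.info(
            "sweep: %s/%s/%s, %d replicates",
            config.transition,
            config.epi_type,
            config.epi_partner,
            config.n_replicates,
        )
    if jobs > 1 and config.n_replicates > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=jobs)(delayed(_run_one)(config, i) for i in indices)
    else:
        rows = [_run_one(config, i) for i in indices]
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(records: pd.DataFrame, path, config: SweepConfig = None, meta_path=None):
    """Write the sweep table as CSV (floats at 12 significant digits) plus an
    optional run-metadata JSON (config echo, package version, master seed)."""
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"output directory does not exist: {directory!r}")
    records.to_csv(path, index=False, float_format="%.12g")
    if meta_path is not None:
        from . import __version__

        meta = {
            "version": __version__,
            "n_rows": int(len(records)),
            "columns": list(records.columns),
        }
        if config is not None:
            meta["config"] = config.to_dict()
            meta["master_seed"] = config.master_seed
        with open(os.fspath(meta_path), "w") as fh:
            json.dump(meta, fh, indent=2)


def read_results(path) -> pd.DataFrame:
    """Read a sweep table written by :func:`write_results`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"results file does not exist: {path!r}")
    return pd.read_csv(path, keep_default_na=True, na_values=[""]).fillna({"error": ""})
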