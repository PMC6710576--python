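"""Full factorial simulation experiment over community structures and rules.

Runs structures x T x L x E x replicates, generating a fresh network for
every replicate (so a default single-structure run draws 12,000 networks:
120 parameter combinations x 100 replicates) and recording the AUC of every
run in a tidy table.  Seeding is derived per run from a stable hash of the
cell labels, so results are reproducible and independent of execution order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import DiffusionParams, run_diffusion
from .netgen import generate_network

__all__ = [
    "GridConfig",
    "derive_seed",
    "run_grid",
    "summarize_cells",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "structure",
    "T",
    "L",
    "E",
    "replicate",
    "network_seed",
    "auc",
    "final_count",
]


def _default_L_values() -> tuple[float, ...]:
    return tuple(round(0.1 * i, 10) for i in range(1, 11))


def _default_E_values() -> tuple[float, ...]:
    return tuple(round(0.05 * i, 10) for i in range(1, 7))


@dataclass
class GridConfig:
    """Configuration of the factorial experiment.

    Defaults follow the study design: 40-individual communities in three
    skew structures, T in {1, 2}, ten L values (0.1..1.0) and six E values
    (0.05..0.30) — 120 (T, L, E) combinations — with 100 replicates each
    over 50 time-steps, seeding the least-connected individuals.
    """

    structures: tuple[str, ...] = ("light", "moderate", "high")
    T_values: tuple[int, ...] = (1, 2)
    L_values: tuple[float, ...] = field(default_factory=_default_L_values)
    E_values: tuple[float, ...] = field(default_factory=_default_E_values)
    replicates: int = 100
    n: int = 40
    n_steps: int = 50
    strategy: str = "least_connected"
    base_seed: int = 0

    def __post_init__(self) -> None:
        self.structures = tuple(self.structures)
        self.T_values = tuple(int(t) for t in self.T_values)
        self.L_values = tuple(float(x) for x in self.L_values)
        self.E_values = tuple(float(x) for x in self.E_values)
        self.validate()

    def validate(self) -> None:
        if not self.structures or not self.T_values or not self.L_values or not self.E_values:
            raise ValueError("grid axes must be non-empty")
        if any(t < 1 for t in self.T_values):
            raise ValueError("all T values must be >= 1")
        if any(not 0.0 <= x <= 1.0 for x in self.L_values):
            raise ValueError("all L values must lie in [0, 1]")
        if any(not 0.0 <= x <= 1.0 for x in self.E_values):
            raise ValueError("all E values must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n < 2 or self.n_steps < 1:
            raise ValueError("need n >= 2 individuals and n_steps >= 1")

    @property
    def n_combinations(self) -> int:
        """Number of (T, L, E) parameter combinations per structure."""
        return len(self.T_values) * len(self.L_values) * len(self.E_values)

    @property
    def n_rows(self) -> int:
        return len(self.structures) * self.n_combinations * self.replicates

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("structures", "T_values", "L_values", "E_values"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GridConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def derive_seed(base_seed: int, *parts) -> int:
    """Stable per-run seed from the cell labels.

    Hashes ``(base_seed, *parts)`` with SHA-256 (floats canonicalised via
    ``%.12g``) and folds to a non-negative 31-bit integer, so every run's
    randomness is independent of execution order and safe to parallelise.
    """
    tokens = [str(int(base_seed))]
    for p in parts:
        if isinstance(p, float):
            tokens.append(format(p, ".12g"))
        else:
            tokens.append(str(p))
    digest = hashlib.sha256("|".join(tokens).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _run_cell(config: GridConfig, structure: str, T: int, L: float, E: float) -> list[dict]:
    params = DiffusionParams(T=T, L=L, E=E, n_steps=config.n_steps)
    rows = []
    for rep in range(config.replicates):
        seed = derive_seed(config.base_seed, structure, T, L, E, rep)
        rng = np.random.default_rng(seed)
        net = generate_network(config.n, structure, rng)
        traj = run_diffusion(net, params, config.strategy, rng)
        rows.append(
            {
                "structure": structure,
                "T": T,
                "L": L,
                "E": E,
                "replicate": rep,
                "network_seed": seed,
                "auc": traj.auc,
                "final_count": traj.final_count,
            }
        )
    return rows


def run_grid(config: GridConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full factorial experiment and return the tidy results table.

    One row per (structure, T, L, E, replicate); a fresh network is generated
    for every replicate.  Fully deterministic given ``base_seed``.
    """
    config.validate()
    rows: list[dict] = []
    for structure in config.structures:
        for T in config.T_values:
            for L in config.L_values:
                for E in config.E_values:
                    cell = _run_cell(config, structure, T, L, E)
                    rows.extend(cell)
                    mean_auc = float(np.mean([r["auc"] for r in cell]))
                    msg = (
                        f"cell structure={structure} T={T} L={L:g} E={E:g} "
                        f"reps={config.replicates} mean_auc={mean_auc:.1f}"
                    )
                    logger.info(msg)
                    if progress:
                        print(msg)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def summarize_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of AUC per (structure, T, L, E) cell."""
    if table.empty:
        raise ValueError("cannot summarise an empty results table")
    out = (
        table.groupby(["structure", "T", "L", "E"], sort=True)["auc"]
        .agg(mean_auc="mean", sd_auc="std", n_replicates="size")
        .reset_index()
    )
    out["sd_auc"] = out["sd_auc"].fillna(0.0)
    return out


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write the results table as CSV with a stable column order."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"results table is missing column(s): {', '.join(missing)}")
    table[RESULT_COLUMNS].to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read and validate a results CSV written by :func:`write_results`."""
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed results file {path}: {exc}") from exc
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"results file {path} is missing column(s): {', '.join(missing)}"
        )
    table = table[RESULT_COLUMNS]
    bad = table.index[(table["auc"] < 0) | (table["final_count"] < 0)]
    if len(bad):
        raise ValueError(
            f"results file {path}: negative auc/final_count at data line {bad[0] + 2}"
        )
    return table
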