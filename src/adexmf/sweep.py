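"""Constrained parameter-grid sweeps with checkpointed execution.

The five swept parameters are the coupling strength S, the two leak
reversal potentials, the mean-field timescale T and the spike-triggered
adaptation increment b_e.  Leak combinations must satisfy the strict
constraint ``E_L_i < E_L_e + 4`` mV; everything else is a full cartesian
product.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .connectome import Connectome
from .features import FEATURE_NAMES, FeatureConfig, extract_features
from .network import SimulationConfig, simulate
from .params import ModelParams

__all__ = [
    "DEFAULT_RANGES",
    "PARAM_ORDER",
    "SweepGrid",
    "generate_grid",
    "run_sweep",
    "paroxysm_census",
]

#: default sweep ranges: S (dimensionless), leak potentials (mV),
#: timescale (ms), adaptation increment (pA)
DEFAULT_RANGES = {
    "S": (0.0, 0.5),
    "E_L_i": (-80.0, -60.0),
    "E_L_e": (-80.0, -60.0),
    "T": (5.0, 40.0),
    "b_e": (0.0, 120.0),
}

PARAM_ORDER = ("S", "E_L_i", "E_L_e", "T", "b_e")

#: strict leak admissibility margin (mV): E_L_i < E_L_e + 4
LEAK_MARGIN = 4.0


@dataclass
class SweepGrid:
    """Enumerated, constraint-filtered parameter grid.

    ``values`` maps each parameter to its value axis; ``indices`` holds one
    row of per-parameter value indices per admissible combination, in
    deterministic lexicographic order over ``PARAM_ORDER``.
    """

    values: dict
    indices: np.ndarray
    constrained: bool = True

    def __len__(self) -> int:
        return self.indices.shape[0]

    @property
    def n_values(self) -> dict:
        return {k: len(v) for k, v in self.values.items()}

    def combination(self, row: int) -> dict:
        idx = self.indices[row]
        return {
            name: float(self.values[name][idx[j]])
            for j, name in enumerate(PARAM_ORDER)
        }

    def as_dataframe(self) -> pd.DataFrame:
        cols = {
            name: np.asarray(self.values[name])[self.indices[:, j]]
            for j, name in enumerate(PARAM_ORDER)
        }
        return pd.DataFrame(cols)


def generate_grid(
    ranges: dict | None = None,
    n_values: int = 16,
    constrained: bool = True,
) -> SweepGrid:
    """Build the evenly spaced (endpoints included) parameter grid.

    With the default ranges and 16 values per parameter the strict leak
    constraint leaves 675,840 of the 16^5 combinations.
    """
    if n_values < 2:
        raise ValueError("n_values must be at least 2")
    if ranges is None:
        ranges = DEFAULT_RANGES
    values = {}
    for name in PARAM_ORDER:
        lo, hi = ranges[name]
        if not lo < hi:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        values[name] = np.linspace(lo, hi, n_values)

    axes = [np.arange(n_values)] * 5
    idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 5)
    if constrained:
        eli = values["E_L_i"][idx[:, PARAM_ORDER.index("E_L_i")]]
        ele = values["E_L_e"][idx[:, PARAM_ORDER.index("E_L_e")]]
        # tolerance keeps the strict inequality exact on the real-number
        # grid: linspace rounding must not readmit boundary-equal pairs
        idx = idx[eli < ele + LEAK_MARGIN - 1e-9]
    return SweepGrid(values=values, indices=idx, constrained=constrained)


def combination_seed(master_seed: int, indices) -> int:
    """Deterministic per-combination seed from the master seed and the
    parameter value indices."""
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(i) for i in indices))
    return int(ss.generate_state(1)[0])


def _run_one(
    combo: dict,
    indices,
    c: Connectome,
    base_cfg: SimulationConfig,
    base_params: ModelParams,
    feature_cfg: FeatureConfig,
    master_seed: int,
) -> dict:
    row = dict(combo)
    row["seed"] = combination_seed(master_seed, indices)
    try:
        p = base_params.replace(
            T=combo["T"], b_e=combo["b_e"],
            E_L_e=combo["E_L_e"], E_L_i=combo["E_L_i"],
        )
        cfg = base_cfg.replace(S=combo["S"], seed=row["seed"])
        ts = simulate(c, cfg, p)
        fs = extract_features(ts, c, feature_cfg)
        row.update(fs.as_dict())
        row["status"] = "ok"
    except Exception as exc:  # per-combination failures never abort the sweep
        for name in FEATURE_NAMES:
            row[name] = np.nan
        row["is_paroxysmal"] = False
        row["status"] = f"error: {exc}"
    return row


_COLUMNS = list(PARAM_ORDER) + ["seed"] + list(FEATURE_NAMES) + [
    "is_paroxysmal", "status",
]


def run_sweep(
    grid: SweepGrid,
    c: Connectome,
    base_cfg: SimulationConfig,
    base_params: ModelParams | None = None,
    workers: int = 1,
    checkpoint_dir=None,
    master_seed: int = 0,
    feature_cfg: FeatureConfig | None = None,
    batch_size: int | None = None,
) -> pd.DataFrame:
    """Simulate and featurize every grid combination.

    Combinations are processed in batches; after each batch the results are
    appended to ``checkpoint_dir/results.csv`` and the completed row ids to
    ``checkpoint_dir/done.json``, so a rerun with the same checkpoint
    directory resumes where it stopped.  Each combination gets a
    deterministic seed derived from ``master_seed`` and its value indices,
    making worker count irrelevant to the results.
    """
    if base_params is None:
        base_params = ModelParams()
    if feature_cfg is None:
        feature_cfg = FeatureConfig()
    if batch_size is None:
        batch_size = max(4 * workers, 16)

    done: set = set()
    results_path = done_path = None
    rows = []
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
        results_path = checkpoint_dir / "results.csv"
        done_path = checkpoint_dir / "done.json"
        if done_path.exists():
            done = set(json.loads(done_path.read_text()))
        if results_path.exists():
            prev = pd.read_csv(results_path)
            rows.extend(prev.to_dict("records"))

    todo = [i for i in range(len(grid)) if i not in done]
    parallel = Parallel(n_jobs=workers) if workers > 1 else None

    for start in range(0, len(todo), batch_size):
        batch = todo[start : start + batch_size]
        jobs = [
            (grid.combination(i), grid.indices[i])
            for i in batch
        ]
        if parallel is not None:
            batch_rows = parallel(
                delayed(_run_one)(
                    combo, idx, c, base_cfg, base_params, feature_cfg, master_seed
                )
                for combo, idx in jobs
            )
        else:
            batch_rows = [
                _run_one(combo, idx, c, base_cfg, base_params, feature_cfg, master_seed)
                for combo, idx in jobs
            ]
        for i, row in zip(batch, batch_rows):
            row["combo_id"] = i
        rows.extend(batch_rows)
        done.update(batch)
        if checkpoint_dir is not None:
            header = not results_path.exists()
            pd.DataFrame(batch_rows).to_csv(
                results_path, mode="a", header=header, index=False
            )
            done_path.write_text(json.dumps(sorted(done)))

    table = pd.DataFrame(rows)
    return table.sort_values("combo_id").reset_index(drop=True)


def paroxysm_census(table: pd.DataFrame) -> tuple:
    """Count paroxysmal runs per (S, E_L_i, E_L_e) cell.

    The remaining two parameters (T, b_e) are marginalized, so each cell is
    bounded by ``n_T * n_be``.  Returns ``(counts, axes)`` where ``axes``
    maps the three parameter names to their sorted value arrays.
    """
    axes = {
        name: np.sort(table[name].unique()) for name in ("S", "E_L_i", "E_L_e")
    }
    shape = tuple(len(axes[n]) for n in ("S", "E_L_i", "E_L_e"))
    counts = np.zeros(shape, dtype=int)
    lookup = {
        name: {v: i for i, v in enumerate(axes[name])}
        for name in axes
    }
    flagged = table[table["is_paroxysmal"].astype(bool)]
    for _, row in flagged.iterrows():
        counts[
            lookup["S"][row["S"]],
            lookup["E_L_i"][row["E_L_i"]],
            lookup["E_L_e"][row["E_L_e"]],
        ] += 1
    return counts, axes
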