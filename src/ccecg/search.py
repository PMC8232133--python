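"""Trend-constrained random search over the architecture grid.

Candidates draw a depth N from {2..7}, a filter vector from
{5,10,15,20,25,30,40,50} and a kernel vector from
{5,10,15,20,25,30,40,50,60,70,85,100}.  Each vector must follow one of
seven admissible trends from first to last block: constant; strictly
increasing; constant then strictly increasing; strictly increasing then
constant; and the three decreasing mirrors.  Candidates must additionally
be shape-feasible for the 1250-sample input and stay within the 250,000
trainable-parameter budget; infeasible draws are rejected and resampled.

Each accepted candidate is trained under identical conditions and ranked
by its validation balanced accuracy; the top record is the selected
architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .arch import GRID_F, GRID_K, GRID_N, HPConfig, PARAMS_CAP, build_model, count_params
from .exceptions import InvalidInputError
from .sim import Dataset
from .training import TrainConfig, train


def validate_trend(values: Sequence[int]) -> bool:
    """True iff the vector follows one of the seven admissible trends.

    Admissible: constant; strictly increasing; constant prefix then
    strictly increasing; strictly increasing then constant suffix; and the
    mirrored decreasing forms.  Equivalently, the step signs must be all
    non-negative or all non-positive, and the non-zero steps must form one
    contiguous run touching the start or the end of the vector.
    """
    v = np.asarray(values)
    if v.ndim != 1 or len(v) < 2:
        return False
    d = np.diff(v)
    if ((d > 0).any() and (d < 0).any()):
        return False
    nz = np.flatnonzero(d != 0)
    if len(nz) == 0:
        return True  # constant
    if not np.array_equal(nz, np.arange(nz[0], nz[-1] + 1)):
        return False  # non-contiguous strict run (e.g. up, flat, up)
    return bool(nz[0] == 0 or nz[-1] == len(d) - 1)


def _sample_trend_vector(rng: np.random.Generator, n: int, grid: Sequence[int]) -> tuple:
    """Draw a length-n vector: uniform over realizable trend scenarios,
    then uniform over grid values compatible with the drawn scenario."""
    grid = sorted(grid)
    scenarios = ["constant", "inc", "dec"]
    if n >= 3:
        scenarios += ["const_inc", "inc_const", "const_dec", "dec_const"]
    scenario = scenarios[rng.integers(len(scenarios))]
    if scenario == "constant":
        return (int(rng.choice(grid)),) * n

    direction_down = scenario in ("dec", "const_dec", "dec_const")
    if scenario in ("inc", "dec"):
        distinct = n
        plateau = 0
    else:
        # plateau of >= 2 equal values at one end, strict run elsewhere
        plateau = int(rng.integers(2, n))      # plateau length in [2, n-1]
        distinct = n - plateau + 1
    values = sorted(int(x) for x in rng.choice(grid, size=distinct, replace=False))
    if scenario in ("inc", "dec"):
        vec = values
    elif scenario in ("const_inc",):
        vec = [values[0]] * plateau + values[1:]
    elif scenario in ("inc_const",):
        vec = values[:-1] + [values[-1]] * plateau
    elif scenario in ("const_dec",):
        vec = [values[-1]] * plateau + values[-2::-1]
    else:  # dec_const
        vec = values[::-1][:-1] + [values[0]] * plateau
    if direction_down and scenario == "dec":
        vec = values[::-1]
    return tuple(vec)


def sample_hp(seed: int) -> HPConfig:
    """Draw one grid-valid, trend-valid, feasible, within-budget candidate.

    Rejection sampling: depth uniform over {2..7}, filter and kernel
    vectors drawn independently by trend scenario, the joint candidate
    rejected until shape feasibility and the parameter cap hold.  The loop
    terminates because minimal constant vectors are always feasible.
    """
    rng = np.random.default_rng(seed)
    while True:
        n = int(rng.choice(GRID_N))
        filters = _sample_trend_vector(rng, n, GRID_F)
        kernels = _sample_trend_vector(rng, n, GRID_K)
        hp = HPConfig(n_blocks=n, filters=filters, kernels=kernels)
        if hp.is_valid():
            return hp


@dataclass(frozen=True)
class SearchRecord:
    """One trained candidate: configuration, size, and validation scores."""

    hp: HPConfig
    params: int
    best_epoch: int
    val_bac: float
    val_se: Optional[float]
    val_sp: Optional[float]
    seed: int


def leaderboard(records: Sequence[SearchRecord]) -> pd.DataFrame:
    """Tabular view of a ranked search (one row per record)."""
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(records) + 1),
            "n_blocks": [r.hp.n_blocks for r in records],
            "filters": ["/".join(map(str, r.hp.filters)) for r in records],
            "kernels": ["/".join(map(str, r.hp.kernels)) for r in records],
            "params": [r.params for r in records],
            "best_epoch": [r.best_epoch for r in records],
            "val_bac": [r.val_bac for r in records],
            "val_se": [r.val_se for r in records],
            "val_sp": [r.val_sp for r in records],
            "seed": [r.seed for r in records],
        }
    )


def run_search(
    n_models: int,
    train_ds: Dataset,
    val_ds: Dataset,
    train_cfg: TrainConfig = TrainConfig(),
    master_seed: int = 0,
) -> List[SearchRecord]:
    """Random search: sample, train, and rank candidates by validation BAC.

    Every candidate is trained under the same protocol with seeds derived
    deterministically from ``master_seed``; records are returned sorted by
    descending validation BAC (ties broken by smaller model, then draw
    order), so the first record is the selected architecture.
    """
    if n_models < 1:
        raise InvalidInputError("n_models must be >= 1")
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise InvalidInputError("empty dataset")
    ss = np.random.SeedSequence(master_seed)
    records = []
    for i, child in enumerate(ss.spawn(n_models)):
        hp_seed, init_seed, fit_seed = (int(s) for s in child.generate_state(3) % (2**31))
        hp = sample_hp(hp_seed)
        model = build_model(hp, init_seed=init_seed)
        cfg = TrainConfig(
            batch_size=train_cfg.batch_size,
            max_epochs=train_cfg.max_epochs,
            early_stop_patience=train_cfg.early_stop_patience,
            learning_rate=train_cfg.learning_rate,
            beta1=train_cfg.beta1,
            beta2=train_cfg.beta2,
            oversample_factor=train_cfg.oversample_factor,
            seed=fit_seed,
        )
        result = train(model, train_ds, val_ds, cfg)
        # Se/Sp of the retained weights at the epoch-metric threshold
        p_val = model.predict_proba(val_ds.waveforms())
        y_val = val_ds.labels()
        pred = p_val >= 0.5
        val_se = (
            float((pred & (y_val == 1)).sum() / (y_val == 1).sum())
            if (y_val == 1).any() else None
        )
        val_sp = (
            float((~pred & (y_val == 0)).sum() / (y_val == 0).sum())
            if (y_val == 0).any() else None
        )
        records.append(
            SearchRecord(
                hp=hp,
                params=count_params(hp),
                best_epoch=result.best_epoch,
                val_bac=result.best_val_bac,
                val_se=val_se,
                val_sp=val_sp,
                seed=hp_seed,
            )
        )
    order = sorted(
        range(len(records)),
        key=lambda i: (-records[i].val_bac, records[i].params, i),
    )
    return [records[i] for i in order]
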