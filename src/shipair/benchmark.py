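"""Desk-scale benchmark configurations shared by tests, scripts and docs.

The *standard* benchmark is a 32 x 32 world (36-km cells, five years, four
months) with the width-16 / 8-residual-block emulator trained for
200 fixed-rate pre-training steps and up to 300 decayed formal steps.  The
*quick* profile shrinks the training budget for multi-seed ablation sweeps.
Problem sizes are deliberately small enough that a full four-month training
run completes in minutes on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from . import emulator as em
from . import synthetic_world as sw

BENCH_NX = 32
BENCH_CELL_KM = 36.0
BENCH_YEARS = 5


@dataclass
class BenchmarkWorld:
    grid: sw.GridSpec
    params: sw.WorldParams
    samples: list

    def train_samples(self, month: str | None = None) -> list:
        out = [s for s in self.samples if not s.is_test]
        if month:
            out = [s for s in out if s.month_label == month]
        return out

    def test_samples(self, month: str | None = None) -> list:
        out = [s for s in self.samples if s.is_test]
        if month:
            out = [s for s in out if s.month_label == month]
        return out

    def baseline_year(self) -> list:
        last = max(s.year_index for s in self.samples)
        return [s for s in self.samples if s.year_index == last]


def benchmark_world(seed: int = 1, nx: int = BENCH_NX) -> BenchmarkWorld:
    grid = sw.build_grid(nx, nx, BENCH_CELL_KM, seed=seed)
    params = sw.WorldParams()
    samples = sw.make_dataset(grid, params, n_years=BENCH_YEARS, seed=seed)
    return BenchmarkWorld(grid=grid, params=params, samples=samples)


def benchmark_train_config(seed: int = 0) -> em.TrainConfig:
    """Standard benchmark training profile (see module docstring)."""
    return em.TrainConfig(
        pretrain_iters=200, pretrain_lr=3e-3,
        formal_max_iters=300, formal_lr0=3e-3, lr_decay=0.99,
        width=16, n_res_blocks=8, seed=seed,
    )


def quick_train_config(seed: int = 0) -> em.TrainConfig:
    """Reduced profile for multi-seed sweeps (ablation ordering)."""
    return em.TrainConfig(
        pretrain_iters=60, pretrain_lr=3e-3,
        formal_max_iters=120, formal_lr0=3e-3, lr_decay=0.99,
        width=16, n_res_blocks=6, seed=seed,
    )


def train_monthly_models(world: BenchmarkWorld, cfg: em.TrainConfig,
                         months: Sequence[str] = sw.MONTHS,
                         with_discriminator: bool = True
                         ) -> Dict[str, em.TrainedEmulator]:
    return {month: em.train_emulator(world.train_samples(month), cfg,
                                     with_discriminator=with_discriminator)
            for month in months}


def spatial_r2(pred: np.ndarray, truth: np.ndarray) -> float:
    """1 - SSE/SST over all cells of one field."""
    sst = float(np.sum((truth - truth.mean()) ** 2))
    return 1.0 - float(np.sum((pred - truth) ** 2)) / sst


def test_year_r2(world: BenchmarkWorld,
                 models: Dict[str, em.TrainedEmulator]) -> Dict[str, float]:
    """Held-out extreme-year shipping-PM2.5 spatial R² per month."""
    out = {}
    for month, model in models.items():
        sample = world.test_samples(month)[0]
        pred = em.predict_shipping_pm(model, sample)
        out[month] = spatial_r2(pred.shipping["pm25"],
                                sample.truth.shipping_pm25())
    return out
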