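"""Ablation variants of the emulator and a per-cell random-forest baseline.

The two ablations are pure loss-weight configurations of the same code path:
"no-gan" keeps the multi-task loss but removes the adversarial term;
"single-task" additionally drops the component-map loss, leaving only the
PM2.5-map error.  The random forest predicts shipping PM2.5 cell by cell
from neighborhood emission sums and point meteorology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .emulator import TrainConfig
from .synthetic_world import LAND_SPECIES, SHIP_SPECIES, MetBundle

#: Variant names understood by :func:`build_variant`.
VARIANTS = ("full", "no-gan", "single-task")


class BaselineError(ValueError):
    pass


def build_variant(name: str, cfg: TrainConfig) -> TrainConfig:
    """Return the training configuration for a named model variant.

    "full" keeps all three loss terms; "no-gan" zeroes the adversarial
    weight; "single-task" zeroes both the adversarial weight and the
    component-map (task 1) weight.
    """
    if name == "full":
        return replace(cfg)
    if name == "no-gan":
        return replace(cfg, w_adv=0.0)
    if name == "single-task":
        return replace(cfg, w_adv=0.0, w_task1=0.0)
    raise BaselineError(f"unknown variant {name!r}; expected one of {VARIANTS}")


@dataclass
class RFConfig:
    n_trees: int = 200
    max_features: int = 10   # predictors sampled per split
    window: int = 3          # odd neighborhood side for emission sums
    cv_folds: int = 10
    cv_repeats: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise BaselineError("n_trees must be >= 1")
        if self.window % 2 == 0 or self.window < 1:
            raise BaselineError("window must be odd and positive")


FEATURE_NAMES = tuple(f"land_{s}_sum" for s in LAND_SPECIES) + \
    tuple(f"ship_{s}_sum" for s in SHIP_SPECIES) + MetBundle.FIELDS


def rf_featurize(samples, window: int = 3) -> pd.DataFrame:
    """One row per (sample, cell): windowed emission sums + point met + target.

    Emission features are the sum of the species field over the window x
    window neighborhood centred on the cell (zero-padded at edges); the five
    met features are cell values.  The target is the truth shipping-related
    PM2.5 at the cell.
    """
    if window % 2 == 0 or window < 1:
        raise BaselineError("window must be odd and positive")
    rows = []
    size = (window, window)
    for s in samples:
        ny, nx = s.met.ws10.shape
        if window > min(ny, nx):
            raise BaselineError("window larger than grid")
        feats = []
        for sp in LAND_SPECIES:
            feats.append(ndimage.uniform_filter(
                s.emissions.land_species(sp), size=size, mode="constant") *
                window ** 2)
        for sp in SHIP_SPECIES:
            feats.append(ndimage.uniform_filter(
                s.emissions.shipping_species(sp), size=size, mode="constant") *
                window ** 2)
        feats += [getattr(s.met, f) for f in MetBundle.FIELDS]
        target = s.truth.shipping_pm25()
        block = np.column_stack([f.ravel() for f in feats] + [target.ravel()])
        rows.append(block)
    table = pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES) + ["target"])
    return table


def rf_train_cv(table: pd.DataFrame, cfg: RFConfig, run_cv: bool = True):
    """Fit the forest on all rows; optionally report repeated-k-fold CV MSE.

    Returns ``(model, cv_summary)`` where ``cv_summary`` is a DataFrame of
    per-(repeat, fold) test mean-squared errors (empty when ``run_cv`` is
    False).  Seeded and deterministic.
    """
    cfg.validate()
    # canonical row order makes the seeded fit invariant to input ordering
    order = np.lexsort(table[list(FEATURE_NAMES) + ["target"]].to_numpy().T)
    table = table.iloc[order]
    X = table[list(FEATURE_NAMES)].to_numpy()
    y = table["target"].to_numpy()
    if np.ptp(y) == 0:
        warnings.warn("constant targets; forest degenerates to the mean",
                      RuntimeWarning)
    records = []
    if run_cv:
        if len(table) < 2 * cfg.cv_folds:
            raise BaselineError("not enough rows for the requested folds")
        splitter = RepeatedKFold(n_splits=cfg.cv_folds, n_repeats=cfg.cv_repeats,
                                 random_state=cfg.seed)
        for i, (tr, te) in enumerate(splitter.split(X)):
            m = _forest(cfg, offset=1 + i)
            m.fit(X[tr], y[tr])
            mse = float(np.mean((m.predict(X[te]) - y[te]) ** 2))
            records.append({"repeat": i // cfg.cv_folds, "fold": i % cfg.cv_folds,
                            "mse": mse})
    model = _forest(cfg, offset=0)
    model.fit(X, y)
    return model, pd.DataFrame(records)


def _forest(cfg: RFConfig, offset: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=min(cfg.max_features, len(FEATURE_NAMES)),
        random_state=cfg.seed + offset,
        n_jobs=1,
    )


def rf_predict_field(model, sample, window: int = 3) -> np.ndarray:
    """Predict a shipping-PM2.5 field for one sample with a fitted forest."""
    table = rf_featurize([sample], window)
    shape = sample.met.ws10.shape
    return model.predict(table[list(FEATURE_NAMES)].to_numpy()).reshape(shape)
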