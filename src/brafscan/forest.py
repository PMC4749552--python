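"""Balanced random-forest protocol for feature-importance estimation.

Cancer occurrence counts are predicted from the seven per-mutation features
with regression forests (40 trees, 4 candidate variables per split), trained
on ~70% of the mutations with the low-count (zero occurrences) and
high-count (nonzero) strata sampled independently so both are represented.
Two sets of 100 runs are performed: one always placing the top hotspot
substitution (V600E) in the training set, one always leaving it out —
forests cannot extrapolate beyond their training response range, so the
placement of the single extreme observation is the protocol's main
sensitivity check.

Per run the test-set Pearson correlation, RMSD, and their ratio
(the performance indicator) are recorded. Feature importance is the total
node-impurity decrease: the summed reduction in residual sum of squares over
every split using the feature, across all trees — averaged over runs and
normalised to percent per set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .codons import MutationKey
from .features import FEATURE_NAMES, find_row

logger = logging.getLogger(__name__)

V600E = MutationKey(position=600, wt_aa="V", mut_aa="E")


class ProtocolInputError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 40
    mtry: int = 4  # candidate variables per split
    n_runs: int = 100
    train_fraction: float = 0.7
    include_v600e_in_training: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.mtry <= len(FEATURE_NAMES):
            raise ProtocolInputError(f"mtry must be in [1, {len(FEATURE_NAMES)}]")
        if not 0 < self.train_fraction < 1:
            raise ProtocolInputError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ForestRun:
    run_id: int
    train_index: tuple[int, ...]
    test_index: tuple[int, ...]
    correlation: float
    rmsd: float
    performance: float
    importances: tuple[float, ...]


@dataclass(frozen=True)
class ProtocolResult:
    runs_with_v600e: tuple[ForestRun, ...]
    runs_without_v600e: tuple[ForestRun, ...]
    mean_importance_pct_with: tuple[float, ...]
    mean_importance_pct_without: tuple[float, ...]

    def importance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "with_v600e": self.mean_importance_pct_with,
                "without_v600e": self.mean_importance_pct_without,
            },
            index=pd.Index(FEATURE_NAMES, name="feature"),
        )

    def runs_table(self) -> pd.DataFrame:
        rows = []
        for label, runs in (
            ("with_v600e", self.runs_with_v600e),
            ("without_v600e", self.runs_without_v600e),
        ):
            for r in runs:
                rows.append(
                    {"set": label, "run": r.run_id, "correlation": r.correlation,
                     "rmsd": r.rmsd, "performance": r.performance}
                )
        return pd.DataFrame(rows)


def balanced_split(
    counts: Sequence[int],
    cfg: ForestConfig,
    rng: np.random.Generator,
    special_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified ~70/30 split, sampling zero-count and nonzero-count mutations
    independently; ``special_index`` is forced into (or out of) the training set
    per ``cfg.include_v600e_in_training``."""
    counts = np.asarray(counts)
    n = counts.size
    strata = [np.flatnonzero(counts == 0), np.flatnonzero(counts > 0)]
    if any(s.size < 2 for s in strata):
        raise ProtocolInputError("each frequency stratum needs >= 2 mutations")
    train_parts = []
    for members in strata:
        n_train = int(round(cfg.train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)  # keep both sides non-empty
        train_parts.append(rng.choice(members, size=n_train, replace=False))
    train = np.sort(np.concatenate(train_parts))
    in_train = np.zeros(n, dtype=bool)
    in_train[train] = True

    if special_index is not None:
        stratum = strata[int(counts[special_index] > 0)]
        if cfg.include_v600e_in_training and not in_train[special_index]:
            # swap with a random training member of the same stratum
            pool = [i for i in stratum if in_train[i] and i != special_index]
            in_train[rng.choice(pool)] = False
            in_train[special_index] = True
        elif not cfg.include_v600e_in_training and in_train[special_index]:
            pool = [i for i in stratum if not in_train[i] and i != special_index]
            in_train[rng.choice(pool)] = True
            in_train[special_index] = False
    return np.flatnonzero(in_train), np.flatnonzero(~in_train)


def fit_forest(
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: ForestConfig,
    random_state: int,
) -> tuple[RandomForestRegressor, np.ndarray]:
    """Fit the regression forest; return it with total-RSS-decrease importances.

    Squared-error trees record the weighted impurity decrease of every split;
    multiplying by the training-set size and summing over trees yields the
    total residual-sum-of-squares decrease attributable to each feature.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ProtocolInputError("need >= 2 training rows")
    model = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.mtry,
        bootstrap=True,
        random_state=random_state,
        n_jobs=1,
    )
    model.fit(X_train, y_train)
    n = X_train.shape[0]
    importances = np.zeros(X_train.shape[1])
    for est in model.estimators_:
        importances += est.tree_.compute_feature_importances(normalize=False) * n
    if np.all(importances == 0):
        logger.warning("constant response: all importances are zero")
    return model, importances


def evaluate_run(
    model: RandomForestRegressor, X_test: np.ndarray, y_test: np.ndarray
) -> tuple[float, float, float]:
    """Test-set (Pearson correlation, RMSD, performance = correlation / RMSD)."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if y_test.size < 3:
        raise ProtocolInputError("need >= 3 test rows")
    predicted = model.predict(X_test)
    if np.std(predicted) == 0 or np.std(y_test) == 0:
        raise UndefinedCorrelationError("constant predictions or response on the test set")
    correlation = float(stats.pearsonr(predicted, y_test).statistic)
    rmsd = float(np.sqrt(np.mean((predicted - y_test) ** 2)))
    performance = correlation / rmsd if rmsd > 0 else math.inf
    return correlation, rmsd, performance


def _run_set(
    X: np.ndarray,
    y: np.ndarray,
    counts: np.ndarray,
    cfg: ForestConfig,
    seed_seq: np.random.SeedSequence,
    special_index: int | None,
) -> tuple[ForestRun, ...]:
    runs = []
    children = seed_seq.spawn(cfg.n_runs)
    for run_id, child in enumerate(children):
        rng = np.random.default_rng(child)
        train, test = balanced_split(counts, cfg, rng, special_index=special_index)
        rf_seed = int(child.generate_state(1)[0] % (2**31))
        model, importances = fit_forest(X[train], y[train], cfg, random_state=rf_seed)
        correlation, rmsd, performance = evaluate_run(model, X[test], y[test])
        runs.append(
            ForestRun(
                run_id=run_id,
                train_index=tuple(int(i) for i in train),
                test_index=tuple(int(i) for i in test),
                correlation=correlation,
                rmsd=rmsd,
                performance=performance,
                importances=tuple(float(v) for v in importances),
            )
        )
    return tuple(runs)


def _mean_importance_pct(runs: Sequence[ForestRun]) -> tuple[float, ...]:
    mean = np.mean([r.importances for r in runs], axis=0)
    total = mean.sum()
    if total == 0:
        return tuple(0.0 for _ in mean)
    return tuple(float(v) for v in 100.0 * mean / total)


def run_protocol(
    X: pd.DataFrame,
    y: pd.Series,
    counts: pd.Series,
    master_seed: int,
    cfg: ForestConfig | None = None,
    hotspot: MutationKey = V600E,
) -> ProtocolResult:
    """Run both 100-forest sets (hotspot in / out of training) from one seed."""
    cfg = cfg or ForestConfig()
    special_index = find_row(X, hotspot)
    if special_index is None:
        logger.warning("hotspot %s not in the matrix; sets differ only by seed", hotspot)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    cv = counts.to_numpy()
    root = np.random.SeedSequence(master_seed)
    seq_with, seq_without = root.spawn(2)
    runs_with = _run_set(
        Xv, yv, cv,
        ForestConfig(**{**cfg.__dict__, "include_v600e_in_training": True}),
        seq_with, special_index,
    )
    runs_without = _run_set(
        Xv, yv, cv,
        ForestConfig(**{**cfg.__dict__, "include_v600e_in_training": False}),
        seq_without, special_index,
    )
    return ProtocolResult(
        runs_with_v600e=runs_with,
        runs_without_v600e=runs_without,
        mean_importance_pct_with=_mean_importance_pct(runs_with),
        mean_importance_pct_without=_mean_importance_pct(runs_without),
    )
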