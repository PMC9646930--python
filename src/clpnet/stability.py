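"""Bootstrap stability: nonparametric edge-weight CIs and case-dropping
correlation-stability (CS) coefficients.

Both routines resample participants (never variables) and derive every
resample's seed deterministically from the master seed and the resample
index, so results do not depend on execution order or worker count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data_model import PanelDataset

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))

#: a statistic maps a dataset to a 1-D labelled vector
StatisticFn = Callable[[PanelDataset], pd.Series]


class StabilityError(RuntimeError):
    pass


@dataclass
class StabilityResult:
    statistic_name: str
    cs_coefficient: float
    drop_grid: tuple[float, ...]
    correlations: dict[float, np.ndarray]
    n_boot: int
    correlation_threshold: float = 0.7
    confidence_level: float = 0.95
    seed: int = 0

    def pass_rate(self, drop: float, threshold: float | None = None) -> float:
        thr = self.correlation_threshold if threshold is None else threshold
        corr = self.correlations[drop]
        return float(np.mean(corr >= thr))

    def recompute_cs(self, threshold: float | None = None,
                     confidence: float | None = None) -> float:
        """CS under alternative cut-offs, reusing the cached bootstrap."""
        thr = self.correlation_threshold if threshold is None else threshold
        conf = self.confidence_level if confidence is None else confidence
        passing = [p for p in self.drop_grid if self.pass_rate(p, thr) >= conf]
        return max(passing) if passing else 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "statistic": self.statistic_name,
            "cs": self.cs_coefficient,
            "grid": list(self.drop_grid),
            "threshold": self.correlation_threshold,
            "confidence_level": self.confidence_level,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "pass_rates": {str(p): self.pass_rate(p) for p in self.drop_grid},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; constant vectors yield -inf (fails any threshold)."""
    if a.size < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return -np.inf
    return float(np.corrcoef(a, b)[0, 1])


def cs_coefficient(data: PanelDataset, statistic: StatisticFn, *,
                   statistic_name: str = "statistic", n_boot: int = 250,
                   drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
                   correlation_threshold: float = 0.7,
                   confidence_level: float = 0.95, seed: int = 0,
                   n_jobs: int = 1) -> StabilityResult:
    """Case-dropping bootstrap CS coefficient of a vector statistic.

    For each drop proportion p, ``n_boot`` subsamples keep
    ``ceil((1 - p) * n)`` participants without replacement; the statistic is
    recomputed and Pearson-correlated with the full-sample value.  CS is the
    largest p for which at least ``confidence_level`` of correlations reach
    ``correlation_threshold`` (0 if none does).  A failing subsample (error
    or constant statistic) counts against the threshold.
    """
    grid = tuple(float(p) for p in drop_grid)
    if any(not 0 < p < 1 for p in grid) or list(grid) != sorted(grid):
        raise StabilityError("drop_grid must be ascending proportions in (0, 1)")
    full = np.asarray(statistic(data), dtype=float)
    n = data.n_participants
    master = np.random.SeedSequence(seed)
    # one child per (drop level, bootstrap index), laid out deterministically
    children = master.spawn(len(grid) * n_boot)

    def one(p_idx: int, b: int) -> float:
        rng = np.random.default_rng(children[p_idx * n_boot + b])
        keep = math.ceil((1.0 - grid[p_idx]) * n)
        rows = rng.choice(n, size=keep, replace=False)
        try:
            sub = np.asarray(statistic(data.subset(rows)), dtype=float)
        except Exception:
            return -np.inf
        return _safe_corr(full, sub)

    tasks = [(pi, b) for pi in range(len(grid)) for b in range(n_boot)]
    if n_jobs == 1:
        flat = [one(pi, b) for pi, b in tasks]
    else:
        flat = Parallel(n_jobs=n_jobs)(delayed(one)(pi, b) for pi, b in tasks)
    correlations = {
        grid[pi]: np.array(flat[pi * n_boot:(pi + 1) * n_boot])
        for pi in range(len(grid))
    }
    result = StabilityResult(statistic_name=statistic_name, cs_coefficient=0.0,
                             drop_grid=grid, correlations=correlations,
                             n_boot=n_boot,
                             correlation_threshold=correlation_threshold,
                             confidence_level=confidence_level, seed=seed)
    result.cs_coefficient = result.recompute_cs()
    return result


def edge_ci_bootstrap(data: PanelDataset, estimator: StatisticFn, *,
                      n_boot: int = 1000, seed: int = 0,
                      confidence_level: float = 0.95,
                      max_failure_rate: float = 0.05,
                      n_jobs: int = 1) -> pd.DataFrame:
    """Nonparametric bootstrap percentile CIs for an edge-weight vector.

    Participants are resampled with replacement and the estimator re-run;
    per-edge quantile CIs surround the full-sample point estimate.  Failed
    resamples are skipped and counted; more than ``max_failure_rate`` of
    them raises :class:`StabilityError`.
    """
    if n_boot < 100:
        raise StabilityError("n_boot must be >= 100")
    point = pd.Series(estimator(data))
    n = data.n_participants
    children = np.random.SeedSequence(seed).spawn(n_boot)

    def one(b: int):
        rng = np.random.default_rng(children[b])
        rows = rng.integers(0, n, size=n)
        try:
            return np.asarray(estimator(data.subset(rows)), dtype=float)
        except Exception:
            return None

    if n_jobs == 1:
        draws = [one(b) for b in range(n_boot)]
    else:
        draws = Parallel(n_jobs=n_jobs)(delayed(one)(b) for b in range(n_boot))
    ok = [d for d in draws if d is not None]
    n_failed = n_boot - len(ok)
    if n_failed > max_failure_rate * n_boot:
        raise StabilityError(f"{n_failed}/{n_boot} bootstrap resamples failed "
                             f"(> {max_failure_rate:.0%} allowed)")
    samples = np.vstack(ok)
    alpha = 1.0 - confidence_level
    lower = np.quantile(samples, alpha / 2, axis=0)
    upper = np.quantile(samples, 1 - alpha / 2, axis=0)
    return pd.DataFrame({
        "edge": point.index,
        "point": point.to_numpy(dtype=float),
        "lower": lower,
        "upper": upper,
    })


# -- statistic factories ---------------------------------------------------

def contemporaneous_edge_statistic(wave: str, config=None) -> StatisticFn:
    from .ggm import estimate_contemporaneous

    def stat(ds: PanelDataset) -> pd.Series:
        return estimate_contemporaneous(ds, wave, config).edge_vector()
    return stat


def temporal_edge_statistic(config=None) -> StatisticFn:
    from .clpn import estimate_temporal

    def stat(ds: PanelDataset) -> pd.Series:
        return estimate_temporal(ds, config).edge_vector()
    return stat


def bridge_ei_statistic(wave: str, clusters, config=None,
                        two_step: bool = False) -> StatisticFn:
    from .centrality import bridge_ei1, bridge_ei2
    from .ggm import estimate_contemporaneous

    def stat(ds: PanelDataset) -> pd.Series:
        net = estimate_contemporaneous(ds, wave, config)
        fn = bridge_ei2 if two_step else bridge_ei1
        nodes = clusters.assigned_nodes()
        return pd.Series([fn(net, clusters, v) for v in nodes], index=nodes)
    return stat


def column_mean_statistic() -> StatisticFn:
    def stat(ds: PanelDataset) -> pd.Series:
        wide = ds.wide()
        return wide.mean(axis=0)
    return stat
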