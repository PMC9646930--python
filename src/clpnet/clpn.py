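"""Directed wave-1 -> wave-2 temporal network via nodewise penalized
regression with baseline adjustment.

Every wave-2 node is regressed on *all* wave-1 nodes (its own baseline
included, which puts autoregressions on the diagonal).  Each regression is
an L1 path over 100 log-spaced penalties with per-node EBIC selection;
coefficients are standardized betas, so entries of ``B`` are comparable
across nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .data_model import PanelDataset, standardize
from .ggm import EstimationConfig, EstimationError


class LassoConvergenceError(EstimationError):
    def __init__(self, lam: float, detail: str):
        self.lam = lam
        super().__init__(f"lasso did not converge near lambda={lam:g}: {detail}")


@dataclass
class LassoSelection:
    """One nodewise regression: selected coefficients plus the path record."""

    coef: np.ndarray
    lambda_selected: float
    lambda_path: np.ndarray
    ebic_path: np.ndarray
    k_selected: int


@dataclass
class TemporalNetwork:
    """Directed coefficient matrix: ``B[i, j]`` is the standardized effect
    of wave-1 node i on wave-2 node j; the diagonal holds autoregressions."""

    B: np.ndarray
    node_labels: tuple[str, ...]
    selections: tuple[LassoSelection, ...]
    n_used: int
    gamma: float

    @property
    def autoregressions(self) -> np.ndarray:
        return np.diag(self.B).copy()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"from_node": self.node_labels[i], "to_node": self.node_labels[j],
             "weight": self.B[i, j]}
            for i in range(self.B.shape[0]) for j in range(self.B.shape[1])
            if self.B[i, j] != 0.0
        ]
        df = pd.DataFrame(rows, columns=["from_node", "to_node", "weight"])
        return df.reindex(df["weight"].abs().sort_values(ascending=False).index
                          ).reset_index(drop=True)

    def edge_vector(self, include_diagonal: bool = True) -> pd.Series:
        p = self.B.shape[0]
        labels, vals = [], []
        for i in range(p):
            for j in range(p):
                if i == j and not include_diagonal:
                    continue
                labels.append(f"{self.node_labels[i]}->{self.node_labels[j]}")
                vals.append(self.B[i, j])
        return pd.Series(vals, index=labels)


def ebic_gaussian(rss: float, n: int, k: int, p: int, gamma: float) -> float:
    """EBIC for a Gaussian regression: n log(RSS/n) + k log n + 2 gamma k log p."""
    return n * np.log(max(rss, 1e-300) / n) + k * np.log(n) + 2.0 * gamma * k * np.log(p)


def lasso_path_regression(y: np.ndarray, X: np.ndarray,
                          config: EstimationConfig | None = None) -> LassoSelection:
    """L1 path + EBIC selection for a single (standardized) response.

    The path holds ``n_lambda`` log-spaced penalties from
    ``lambda_max = max |X'y| / n`` down to ``lambda_max * lambda_min_ratio``;
    the minimum-EBIC fit is returned (ties go to the larger penalty).
    """
    config = config or EstimationConfig()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and X have incompatible shapes")
    if np.isnan(y).any() or np.isnan(X).any():
        raise EstimationError("lasso_path_regression requires complete rows")

    lam_max = float(np.max(np.abs(X.T @ y)) / n)
    if lam_max <= 0:
        lam_max = 1e-3
    path = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)

    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            alphas, coefs, _ = lasso_path(X, y, alphas=path, max_iter=50_000,
                                          tol=1e-8)
        except ConvergenceWarning as exc:  # pragma: no cover - rare
            raise LassoConvergenceError(float(path[-1]), str(exc)) from exc
    # sklearn returns the path sorted by descending alpha, matching ours
    ebics = np.empty(len(alphas))
    for i in range(len(alphas)):
        b = coefs[:, i]
        rss = float(np.sum((y - X @ b) ** 2))
        k = int(np.count_nonzero(b))
        ebics[i] = ebic_gaussian(rss, n, k, p, config.gamma)
    best = int(np.argmin(ebics))
    return LassoSelection(coef=coefs[:, best].copy(),
                          lambda_selected=float(alphas[best]),
                          lambda_path=np.asarray(alphas),
                          ebic_path=ebics,
                          k_selected=int(np.count_nonzero(coefs[:, best])))


def estimate_temporal(data: PanelDataset,
                      config: EstimationConfig | None = None) -> TemporalNetwork:
    """Cross-lagged panel network over exactly two waves of complete data.

    Column j of the result comes from one regression of the standardized
    wave-2 node j on all standardized wave-1 nodes; zero entries are exact.
    """
    config = config or EstimationConfig()
    if data.n_waves != 2:
        raise EstimationError(f"temporal estimation requires exactly 2 waves, "
                              f"got {data.n_waves}")
    if not data.is_complete:
        raise EstimationError("estimate_temporal requires complete data; impute first")
    z = data if data.standardized else standardize(data)
    X = z.wave_matrix(z.wave_labels[0])
    Y = z.wave_matrix(z.wave_labels[1])
    p = data.n_variables
    B = np.zeros((p, p))
    selections = []
    for j in range(p):
        sel = lasso_path_regression(Y[:, j], X, config)
        B[:, j] = sel.coef
        selections.append(sel)
    return TemporalNetwork(B=B, node_labels=data.variable_names,
                           selections=tuple(selections),
                           n_used=data.n_participants, gamma=config.gamma)
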