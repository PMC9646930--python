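"""Two-wave panel simulator with known contemporaneous and cross-lagged
structure, covariate confounding, and MAR missingness.

The generative model is latent-Gaussian: wave 1 is drawn from a
multivariate normal with a known sparse precision matrix, wave 2 is a
linear cross-lagged map of wave 1 plus innovation noise, and each latent
column is affinely mapped into its instrument's score range (latent +-3 sd
spans the scale, then clipped; the clipping fraction is < 1%).  Missingness
is imposed on wave-2 cells only, with probability driven by observed
wave-1 covariates through a logistic link (MAR) or constant (MCAR).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data_model import PanelDataset, VariableSpec, default_schema

#: overall missing fraction matching the motivating cohort
DEFAULT_MISSING_RATE = 0.292

_PD_EIG_FLOOR = 1e-6
_MAX_REPAIR = 50


class GenerationError(RuntimeError):
    """Requested structure could not be made positive definite."""


def _pcor_from_precision(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


@dataclass
class SimTruth:
    """Ground truth for one simulated study.

    Attributes
    ----------
    omega:
        True wave-1 precision matrix (symmetric positive definite).
    pcor_true:
        Implied partial-correlation matrix (unit diagonal).
    B_true:
        Cross-lagged coefficient matrix; entry ``[i, j]`` is the effect of
        wave-1 node *i* on wave-2 node *j* (autoregressions on the diagonal).
    noise_sd:
        Per-node wave-2 innovation standard deviation (latent scale).
    missing_rate:
        Target overall missing fraction across all cells of both waves.
    missing_mechanism:
        ``"MAR"`` (logistic on wave-1 covariates) or ``"MCAR"``.
    seed:
        Seed for all randomness downstream of this truth.
    """

    omega: np.ndarray
    B_true: np.ndarray
    noise_sd: np.ndarray
    missing_rate: float = DEFAULT_MISSING_RATE
    missing_mechanism: str = "MAR"
    seed: int = 0
    pcor_true: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.B_true = np.asarray(self.B_true, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if not np.allclose(self.omega, self.omega.T, atol=1e-12):
            raise GenerationError("omega must be symmetric")
        if np.linalg.eigvalsh(self.omega).min() <= 0:
            raise GenerationError("omega must be positive definite")
        if not 0 <= self.missing_rate < 1:
            raise GenerationError("missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in ("MAR", "MCAR"):
            raise GenerationError(f"unknown missing mechanism {self.missing_mechanism!r}")
        if self.pcor_true is None:
            self.pcor_true = _pcor_from_precision(self.omega)

    @property
    def n_nodes(self) -> int:
        return self.omega.shape[0]

    def sigma1(self) -> np.ndarray:
        """Wave-1 covariance implied by omega, rescaled to a correlation."""
        cov = np.linalg.inv(self.omega)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "omega": self.omega.tolist(),
            "pcor_true": self.pcor_true.tolist(),
            "B_true": self.B_true.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "missing_rate": self.missing_rate,
            "missing_mechanism": self.missing_mechanism,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(omega=np.array(d["omega"]), B_true=np.array(d["B_true"]),
                   noise_sd=np.array(d["noise_sd"]), missing_rate=d["missing_rate"],
                   missing_mechanism=d["missing_mechanism"], seed=d["seed"])


def make_truth(n_symptom: int = 5, n_cognition: int = 4, n_covariate: int = 4,
               density: float = 0.2, effect_range: tuple[float, float] = (0.1, 0.3),
               seed: int = 0, *, ar_range: tuple[float, float] = (0.3, 0.8),
               cross_density: float | None = None,
               missing_rate: float = DEFAULT_MISSING_RATE,
               missing_mechanism: str = "MAR") -> SimTruth:
    """Sample a sparse ground-truth structure for the simulator.

    ``density`` controls the fraction of nonzero upper-triangle partial
    correlations (drawn with magnitudes in ``effect_range`` and random
    signs).  The precision matrix is repaired toward positive definiteness
    by shrinking off-diagonals by 0.9 per iteration (at most 50 times),
    then the implied partial correlations are recomputed so the returned
    ``pcor_true`` is always exactly consistent with ``omega``.

    ``B_true`` gets autoregressions uniform in ``ar_range`` on the diagonal
    and sparse cross-lags (support density ``cross_density``, default
    ``density``) with magnitudes in ``effect_range``.
    """
    if not 0 <= density <= 1:
        raise GenerationError("density must lie in [0, 1]")
    lo, hi = effect_range
    if not (-1 < lo < 1 and -1 < hi < 1 and lo <= hi):
        raise GenerationError("effect_range must be within (-1, 1)")
    rng = np.random.default_rng(seed)
    p = n_symptom + n_cognition + n_covariate

    iu = np.triu_indices(p, 1)
    n_pairs = iu[0].size
    n_edges = int(round(density * n_pairs))
    pcor = np.zeros((p, p))
    if n_edges:
        pick = rng.choice(n_pairs, size=n_edges, replace=False)
        mags = rng.uniform(abs(lo), abs(hi), size=n_edges)
        signs = rng.choice([-1.0, 1.0], size=n_edges)
        pcor[iu[0][pick], iu[1][pick]] = mags * signs
        pcor = pcor + pcor.T

    omega = np.eye(p) - pcor
    np.fill_diagonal(omega, 1.0)
    for _ in range(_MAX_REPAIR):
        if np.linalg.eigvalsh(omega).min() > _PD_EIG_FLOOR:
            break
        off = omega - np.diag(np.diag(omega))
        omega = np.diag(np.diag(omega)) + 0.9 * off
    else:
        raise GenerationError(
            f"could not reach positive definiteness in {_MAX_REPAIR} repair steps "
            f"(density={density}, effect_range={effect_range})")

    B = np.zeros((p, p))
    np.fill_diagonal(B, rng.uniform(*ar_range, size=p))
    cd = density if cross_density is None else cross_density
    offpairs = [(i, j) for i in range(p) for j in range(p) if i != j]
    n_cross = int(round(cd * len(offpairs)))
    if n_cross:
        pick = rng.choice(len(offpairs), size=n_cross, replace=False)
        for k in pick:
            i, j = offpairs[k]
            B[i, j] = rng.uniform(abs(lo), abs(hi)) * rng.choice([-1.0, 1.0])

    truth = SimTruth(omega=omega, B_true=B, noise_sd=np.ones(p),
                     missing_rate=missing_rate, missing_mechanism=missing_mechanism,
                     seed=seed)
    # innovation sd keeps the latent wave-2 variance near 1 per node
    sigma1 = truth.sigma1()
    var2 = np.einsum("ij,ik,kj->j", B, sigma1, B)
    truth.noise_sd = np.sqrt(np.clip(1.0 - var2, 0.05, None))
    return truth


@dataclass
class SimulationResult:
    """Masked dataset plus everything a recovery test needs.

    ``dataset`` has the MAR/MCAR mask applied; ``complete`` is the same
    draw before masking.  ``mask_prob`` records the per-participant wave-2
    missingness probability (a deterministic function of observed wave-1
    covariates), so the mask-generating inputs are fully observable.
    """

    dataset: PanelDataset
    complete: PanelDataset
    truth: SimTruth
    mask_prob: np.ndarray
    mar_drivers: tuple[str, ...]


def _calibrate_intercept(z: np.ndarray, target: float, slope: float = 1.0) -> float:
    """Intercept a such that mean(expit(a + slope*z)) == target."""
    f = lambda a: float(np.mean(expit(a + slope * z))) - target
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def simulate_panel(truth: SimTruth, n: int,
                   schema: Sequence[VariableSpec] | None = None,
                   wave_labels: tuple[str, str] = ("w1", "w2"),
                   seed: int | None = None) -> SimulationResult:
    """Draw a two-wave panel of ``n`` participants from ``truth``.

    Wave 1 comes from the multivariate normal implied by ``truth.omega``
    (unit variances); wave 2 is ``B_true' * wave1`` plus innovation noise.
    Columns are affine-mapped so that latent +-3 sd spans each variable's
    score range, then clipped; ordinal variables are additionally rounded
    to their levels.  Missingness hits wave-2 cells only, calibrated so the
    overall missing fraction across both waves approximates
    ``truth.missing_rate``.
    """
    schema = tuple(schema) if schema is not None else default_schema()
    p = truth.n_nodes
    if len(schema) != p:
        raise ValueError(f"schema lists {len(schema)} variables but truth has {p} nodes")
    if n < 10 * p:
        raise ValueError(f"n must be >= 10 * nodes ({10 * p}); got {n}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    sigma1 = truth.sigma1()
    L = np.linalg.cholesky(sigma1)
    z1 = rng.standard_normal((n, p)) @ L.T
    z2 = z1 @ truth.B_true + rng.standard_normal((n, p)) * truth.noise_sd

    values = np.empty((n, p, 2))
    for j, v in enumerate(schema):
        mid = 0.5 * (v.scale_min + v.scale_max)
        half = 0.5 * (v.scale_max - v.scale_min)
        for w, z in enumerate((z1, z2)):
            col = mid + z[:, j] * (half / 3.0)
            col = np.clip(col, v.scale_min, v.scale_max)
            if v.ordinal_levels is not None:
                col = np.clip(np.round(col), v.scale_min, v.scale_max)
            values[:, j, w] = col

    complete = PanelDataset(values.copy(), schema, wave_labels)

    drivers: tuple[str, ...] = ()
    if truth.missing_rate > 0:
        # all missingness concentrated in wave 2: per-cell probability must
        # be missing_rate * (total cells) / (wave-2 cells)
        q = truth.missing_rate * 2.0
        if q >= 0.95:
            raise GenerationError(f"missing_rate {truth.missing_rate} too high for "
                                  "wave-2-only masking")
        if truth.missing_mechanism == "MAR":
            cov_idx = [j for j, v in enumerate(schema) if v.role == "covariate"]
            drv = cov_idx[:2] if len(cov_idx) >= 2 else cov_idx or [0]
            drivers = tuple(schema[j].name for j in drv)
            zdrv = np.zeros(n)
            for j in drv:
                col = values[:, j, 0]
                zdrv += (col - col.mean()) / col.std()
            a = _calibrate_intercept(zdrv, q)
            prob = expit(a + zdrv)
        else:
            prob = np.full(n, q)
        mask2 = rng.random((n, p)) < prob[:, None]
        values[:, :, 1][mask2] = np.nan
        mask_prob = prob
    else:
        mask_prob = np.zeros(n)

    dataset = PanelDataset(values, schema, wave_labels)
    return SimulationResult(dataset=dataset, complete=complete, truth=truth,
                            mask_prob=mask_prob, mar_drivers=drivers)
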