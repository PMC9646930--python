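"""End-to-end orchestration: simulate -> impute -> estimate -> centrality
-> stability, from a single YAML config with one master seed.

Every run writes a self-describing ``manifest.json`` (config with all
defaults filled in, config hash, seed, library versions, per-stage wall
time) plus machine-readable artifacts; the same seed and config always
reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import ClusterAssignment, centrality_table
from .clpn import TemporalNetwork, estimate_temporal
from .data_model import (PanelDataset, VariableSpec, default_schema, describe,
                         read_panel, write_panel)
from .export import (CSV_FLOAT_FORMAT, contemporaneous_metadata,
                     contemporaneous_to_graphml, temporal_metadata,
                     temporal_to_graphml, write_csv, write_json)
from .ggm import ContemporaneousNetwork, EstimationConfig, estimate_contemporaneous
from .impute import mice_impute
from .stability import (DEFAULT_DROP_GRID, contemporaneous_edge_statistic,
                        cs_coefficient, edge_ci_bootstrap)
from .synthetic import SimTruth, make_truth, simulate_panel

log = logging.getLogger("clpnet")

ARTIFACT_NAMES = (
    "descriptives",
    "contemporaneous_w1_edges",
    "contemporaneous_w2_edges",
    "temporal_edges",
    "centrality",
    "edge_ci_w1",
    "stability_cs",
)


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 1)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 2)."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    input: str | None = None
    simulation: dict | None = None
    imputation: dict = field(default_factory=dict)
    estimation: dict = field(default_factory=dict)
    stability: dict = field(default_factory=dict)
    pool: str = "cells"

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulation is None):
            raise ConfigError("exactly one of 'input' and 'simulation' must be set")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.pool not in ("cells", "networks"):
            raise ConfigError(f"pool must be 'cells' or 'networks', got {self.pool!r}")
        sim_keys = {"n", "n_symptom", "n_cognition", "n_covariate", "density",
                    "effect_range", "cross_density", "missing_rate",
                    "missing_mechanism"}
        if self.simulation is not None:
            unknown = set(self.simulation) - sim_keys
            if unknown:
                raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        imp_keys = {"m", "n_iter", "k_donors"}
        unknown = set(self.imputation) - imp_keys
        if unknown:
            raise ConfigError(f"unknown imputation keys: {sorted(unknown)}")
        est_keys = {"gamma", "n_lambda", "lambda_min_ratio", "correlation_method"}
        unknown = set(self.estimation) - est_keys
        if unknown:
            raise ConfigError(f"unknown estimation keys: {sorted(unknown)}")
        stab_keys = {"n_boot_ci", "n_boot_cs", "drop_grid"}
        unknown = set(self.stability) - stab_keys
        if unknown:
            raise ConfigError(f"unknown stability keys: {sorted(unknown)}")

    def resolved(self) -> dict:
        """Config with every default filled in (recorded in the manifest)."""
        sim = None
        if self.simulation is not None:
            sim = {"n": 2000, "n_symptom": 5, "n_cognition": 4, "n_covariate": 4,
                   "density": 0.2, "effect_range": [0.1, 0.3], "cross_density": 0.05,
                   "missing_rate": 0.292, "missing_mechanism": "MAR"}
            sim.update(self.simulation)
        imp = {"m": 10, "n_iter": 20, "k_donors": 5}
        imp.update(self.imputation)
        est = {"gamma": 0.5, "n_lambda": 100, "lambda_min_ratio": 0.01,
               "correlation_method": "pearson"}
        est.update(self.estimation)
        stab = {"n_boot_ci": 1000, "n_boot_cs": 250,
                "drop_grid": [float(p) for p in DEFAULT_DROP_GRID]}
        stab.update(self.stability)
        return {"seed": self.seed, "out_dir": self.out_dir, "input": self.input,
                "simulation": sim, "imputation": imp, "estimation": est,
                "stability": stab, "pool": self.pool}


def load_config(path: str | Path, *, seed: int | None = None,
                out_dir: str | None = None) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {"seed", "out_dir", "input", "simulation", "imputation",
             "estimation", "stability", "pool"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if seed is not None:
        raw["seed"] = seed
    if out_dir is not None:
        raw["out_dir"] = out_dir
    if "seed" not in raw or raw["seed"] is None:
        raise ConfigError("seed is mandatory")
    raw.setdefault("out_dir", "clpnet_run")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def generic_schema(n_symptom: int, n_cognition: int,
                   n_covariate: int) -> tuple[VariableSpec, ...]:
    """Placeholder schema when the node counts differ from the default
    13-variable layout."""
    specs = [VariableSpec(f"s{i + 1}", "symptom", 0, 10) for i in range(n_symptom)]
    specs += [VariableSpec(f"c{i + 1}", "cognition", 0, 10) for i in range(n_cognition)]
    specs += [VariableSpec(f"v{i + 1}", "covariate", 0, 10) for i in range(n_covariate)]
    return tuple(specs)


def _config_hash(resolved: dict) -> str:
    blob = json.dumps(resolved, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _versions() -> dict:
    import networkx
    import scipy
    import sklearn
    return {"clpnet": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__, "networkx": networkx.__version__,
            "python": sys.version.split()[0]}


@dataclass
class RunResult:
    manifest: dict
    out_dir: Path
    data: PanelDataset
    truth: SimTruth | None
    net_w1: ContemporaneousNetwork
    net_w2: ContemporaneousNetwork
    tnet: TemporalNetwork
    centrality: pd.DataFrame


def _average_contemporaneous(nets: list[ContemporaneousNetwork]) -> ContemporaneousNetwork:
    first = nets[0]
    pcor = np.mean([n.pcor for n in nets], axis=0)
    return ContemporaneousNetwork(
        pcor=pcor, node_labels=first.node_labels,
        lambda_selected=float(np.mean([n.lambda_selected for n in nets])),
        lambda_path=first.lambda_path, ebic_path=first.ebic_path,
        edge_counts=first.edge_counts, n_used=first.n_used,
        wave_label=first.wave_label, gamma=first.gamma)


def _average_temporal(nets: list[TemporalNetwork]) -> TemporalNetwork:
    first = nets[0]
    B = np.mean([n.B for n in nets], axis=0)
    return TemporalNetwork(B=B, node_labels=first.node_labels,
                           selections=first.selections, n_used=first.n_used,
                           gamma=first.gamma)


def run_full(config: RunConfig) -> RunResult:
    """Execute every stage and write all artifacts plus the manifest.

    On stage failure the manifest records partial completion and the
    failing stage's error before :class:`StageError` propagates.
    """
    resolved = config.resolved()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": resolved,
        "config_hash": _config_hash(resolved),
        "seed": config.seed,
        "versions": _versions(),
        "stages": [],
        "artifacts": {},
        "status": "running",
    }
    state: dict = {}

    def stage(name, fn):
        log.info("stage %s: start", name)
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            manifest["stages"].append({"name": name, "status": "failed",
                                       "seconds": time.perf_counter() - t0,
                                       "error": f"{type(exc).__name__}: {exc}"})
            manifest["status"] = f"failed at {name}"
            write_json(manifest, out / "manifest.json")
            raise StageError(name, exc) from exc
        dt = time.perf_counter() - t0
        manifest["stages"].append({"name": name, "status": "ok", "seconds": dt})
        log.info("stage %s: done in %.2fs", name, dt)

    def art(name: str, filename: str) -> Path:
        manifest["artifacts"][name] = filename
        return out / filename

    # -- load or simulate ---------------------------------------------------
    def s_data():
        if config.input is not None:
            state["data"] = read_panel(config.input, default_schema())
            state["truth"] = None
        else:
            sim = resolved["simulation"]
            counts = (sim["n_symptom"], sim["n_cognition"], sim["n_covariate"])
            schema = default_schema() if counts == (5, 4, 4) else generic_schema(*counts)
            truth = make_truth(*counts, density=sim["density"],
                               effect_range=tuple(sim["effect_range"]),
                               seed=config.seed,
                               cross_density=sim["cross_density"],
                               missing_rate=sim["missing_rate"],
                               missing_mechanism=sim["missing_mechanism"])
            res = simulate_panel(truth, sim["n"], schema)
            state["data"] = res.dataset
            state["truth"] = truth
            write_panel(res.dataset, out / "panel.csv")
            truth.to_json(out / "truth.json")
            manifest["truth_file"] = "truth.json"
        state["schema"] = state["data"].variables
        state["clusters"] = ClusterAssignment.from_roles(state["schema"])

    def s_describe():
        write_csv(describe(state["data"]), art("descriptives", "descriptives.csv"))

    def s_impute():
        imp = resolved["imputation"]
        if state["data"].is_complete:
            state["imputed"] = state["data"]
            state["completed"] = [state["data"]]
        else:
            result = mice_impute(state["data"], m=imp["m"], n_iter=imp["n_iter"],
                                 seed=config.seed + 1, k_donors=imp["k_donors"])
            state["imputed"] = result.aggregated
            state["completed"] = result.completed
        write_panel(state["imputed"], out / "imputed.csv")

    def s_contemporaneous():
        est = EstimationConfig(**resolved["estimation"])
        for wave, name in (("w1", "contemporaneous_w1_edges"),
                           ("w2", "contemporaneous_w2_edges")):
            if config.pool == "networks" and len(state["completed"]) > 1:
                nets = [estimate_contemporaneous(ds, wave, est)
                        for ds in state["completed"]]
                net = _average_contemporaneous(nets)
            else:
                net = estimate_contemporaneous(state["imputed"], wave, est)
            state[f"net_{wave}"] = net
            write_csv(net.edge_list(), art(name, f"{name}.csv"))
            contemporaneous_to_graphml(net, state["clusters"],
                                       out / f"contemporaneous_{wave}.graphml")
            write_json(contemporaneous_metadata(net),
                       out / f"contemporaneous_{wave}_meta.json")

    def s_temporal():
        est = EstimationConfig(**resolved["estimation"])
        if config.pool == "networks" and len(state["completed"]) > 1:
            nets = [estimate_temporal(ds, est) for ds in state["completed"]]
            tnet = _average_temporal(nets)
        else:
            tnet = estimate_temporal(state["imputed"], est)
        state["tnet"] = tnet
        write_csv(tnet.edge_list(), art("temporal_edges", "temporal_edges.csv"))
        temporal_to_graphml(tnet, state["clusters"], out / "temporal.graphml")
        write_json(temporal_metadata(tnet), out / "temporal_meta.json")

    def s_centrality():
        table = centrality_table(state["net_w1"], state["tnet"], state["imputed"],
                                 state["clusters"])
        state["centrality"] = table
        write_csv(table, art("centrality", "centrality.csv"))

    def s_stability():
        stab = resolved["stability"]
        est = EstimationConfig(**resolved["estimation"])
        estimator = contemporaneous_edge_statistic("w1", est)
        ci = edge_ci_bootstrap(state["imputed"], estimator,
                               n_boot=stab["n_boot_ci"], seed=config.seed + 2)
        write_csv(ci, art("edge_ci_w1", "edge_ci_w1.csv"))
        cs = cs_coefficient(state["imputed"], estimator,
                            statistic_name="contemporaneous_w1_edges",
                            n_boot=stab["n_boot_cs"],
                            drop_grid=stab["drop_grid"], seed=config.seed + 3)
        cs.to_json(art("stability_cs", "stability_cs.json"))

    stage("data", s_data)
    stage("describe", s_describe)
    stage("impute", s_impute)
    stage("contemporaneous", s_contemporaneous)
    stage("temporal", s_temporal)
    stage("centrality", s_centrality)
    stage("stability", s_stability)

    manifest["status"] = "complete"
    write_json(manifest, out / "manifest.json")
    return RunResult(manifest=manifest, out_dir=out, data=state["data"],
                     truth=state["truth"], net_w1=state["net_w1"],
                     net_w2=state["net_w2"], tnet=state["tnet"],
                     centrality=state["centrality"])


# -- truth recovery --------------------------------------------------------

def _recovery_metrics(est: np.ndarray, true: np.ndarray,
                      entries: tuple[np.ndarray, np.ndarray]) -> dict:
    e = est[entries]
    t = true[entries]
    true_nz = t != 0
    est_nz = e != 0
    out: dict = {"n_true_edges": int(true_nz.sum()),
                 "n_estimated_edges": int(est_nz.sum()),
                 "false_positives": int((est_nz & ~true_nz).sum())}
    if true_nz.any():
        out["sensitivity"] = float(np.mean(est_nz[true_nz]))
        both = true_nz & est_nz
        out["sign_agreement"] = (float(np.mean(np.sign(e[both]) == np.sign(t[both])))
                                 if both.any() else None)
        if true_nz.sum() >= 2 and np.std(t[true_nz]) > 0 and np.std(e[true_nz]) > 0:
            out["weight_correlation"] = float(np.corrcoef(e[true_nz], t[true_nz])[0, 1])
        else:
            out["weight_correlation"] = None
        out["sensitivity_defined"] = True
    else:
        out["sensitivity"] = None
        out["sign_agreement"] = None
        out["weight_correlation"] = None
        out["sensitivity_defined"] = False
    denom = (~true_nz).sum()
    out["specificity"] = float(np.mean(~est_nz[~true_nz])) if denom else None
    return out


def recover_truth_report(run: RunResult | str | Path, truth: SimTruth | None = None) -> dict:
    """Compare a run's estimated networks with the generating truth.

    Accepts an in-memory :class:`RunResult` or a path to a run directory
    containing ``manifest.json``.  Raises :class:`ConfigError` when the run
    has no stored truth and none is supplied.
    """
    if isinstance(run, (str, Path)):
        out = Path(run)
        manifest = json.loads((out / "manifest.json").read_text())
        if truth is None:
            if "truth_file" not in manifest:
                raise ConfigError("run manifest has no truth reference; "
                                  "pass the truth explicitly")
            truth = SimTruth.from_json(out / manifest["truth_file"])
        meta1 = json.loads((out / "contemporaneous_w1_meta.json").read_text())
        pcor = np.asarray(meta1["pcor"])
        tmeta = json.loads((out / "temporal_meta.json").read_text())
        B = np.asarray(tmeta["B"])
    else:
        if truth is None:
            truth = run.truth
        if truth is None:
            raise ConfigError("run has no stored truth; pass it explicitly")
        pcor = run.net_w1.pcor
        B = run.tnet.B

    p = pcor.shape[0]
    iu = np.triu_indices(p, 1)
    offdiag = np.where(~np.eye(p, dtype=bool))
    report = {
        "contemporaneous": _recovery_metrics(pcor, truth.pcor_true, iu),
        "temporal_cross": _recovery_metrics(B, truth.B_true
                                            - np.diag(np.diag(truth.B_true)), offdiag),
        "autoregression_correlation": None,
    }
    d_est, d_true = np.diag(B), np.diag(truth.B_true)
    if np.std(d_true) > 0 and np.std(d_est) > 0:
        report["autoregression_correlation"] = float(np.corrcoef(d_est, d_true)[0, 1])
    return report
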