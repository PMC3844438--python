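"""Experiment configuration: serializable schema, hashing, dispatch.

An :class:`ExperimentConfig` captures everything one run needs — network
parameters, the coding-ratio distribution, replay settings and the master
seed — and round-trips losslessly through YAML/JSON.  ``run_experiment``
executes one named experiment and writes a tidy CSV plus a JSON sidecar with
the full config and its hash, so every output artifact is traceable to the
exact settings that produced it.  Identical (config, seed) pairs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, connectivity, meanfield, network
from .distributions import CodingRatioSpec, sample_phi

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]

EXPERIMENTS = ("replay", "success", "phase", "capacity", "scatter", "validate_network")


@dataclass
class ExperimentConfig:
    experiment: str
    distribution: dict = field(
        default_factory=lambda: {"family": "gamma", "phi0": 0.01, "sigma_phi": 0.001}
    )
    N: int = 100_000
    cm: float = 0.1
    theta: float | None = 26.0
    theta_grid: list | None = None
    c_target: float | None = 0.05
    P: int | None = None
    b_override: float | None = None
    inhibition: str = "linear"
    Q: int = 100
    n_real: int = 100
    t_eval: int = 100
    phi_grid: list | None = None
    P_grid: list | None = None
    seed: int = 0
    outdir: str = "."

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; one of {EXPERIMENTS}")
        if self.c_target is not None and self.c_target >= self.cm:
            raise ValueError("c_target must be below cm")
        if self.c_target is None and self.P is None:
            raise ValueError("one of c_target and P must be set")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def spec(self) -> CodingRatioSpec:
        return CodingRatioSpec.from_dict(self.distribution)


def _write(cfg: ExperimentConfig, frame: pd.DataFrame, meta: dict) -> dict:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{cfg.experiment}_{cfg.config_hash}"
    csv_path = outdir / f"{stem}.csv"
    json_path = outdir / f"{stem}.json"
    frame.to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {"config": cfg.to_dict(), "config_hash": cfg.config_hash, **meta}
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True, default=float))
    return {"csv": str(csv_path), "json": str(json_path)}


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run one experiment and write its CSV + JSON sidecar; returns the paths."""
    spec = cfg.spec()
    meta: dict = {}

    if cfg.experiment == "replay":
        if cfg.c_target is not None:
            P, phi = connectivity.calibrate_P(
                spec, cfg.c_target, cfg.cm, "per_realization", seed=cfg.seed, N=cfg.N
            )
        else:
            phi = sample_phi(spec, cfg.P, cfg.N, cfg.seed)
        p = meanfield.params_for_phi(
            phi, cfg.cm, cfg.theta, cfg.inhibition,
            phi0=spec.phi0 if cfg.inhibition == "nonlinear" else None,
            b=cfg.b_override,
        )
        trace = meanfield.run_replay(phi, p, cfg.Q)
        frame = trace.to_frame()
        meta["P"] = int(phi.P)
        meta["varsigma"] = p.varsigma

    elif cfg.experiment == "success":
        curve = analysis.success_rate(
            spec, N=cfg.N, cm=cfg.cm, theta=cfg.theta, Q=cfg.Q,
            n_real=cfg.n_real, seed=cfg.seed, P=cfg.P, c_target=cfg.c_target,
            inhibition=cfg.inhibition,
            phi0=spec.phi0 if cfg.inhibition == "nonlinear" else None,
        )
        frame = curve.to_frame()
        meta["T90"] = analysis.t90(curve)

    elif cfg.experiment == "phase":
        phi_grid = cfg.phi_grid or [0.004, 0.006, 0.008, 0.01, 0.012, 0.014]
        theta_grid = cfg.theta_grid or list(range(10, 41, 2))
        rel = spec.sigma_phi / spec.phi0

        def spec_for(phi0):
            d = dict(cfg.distribution)
            if d.get("family") == "triangular":
                d["phi_max"] = phi0
                d.pop("phi0", None)
                d["sigma_phi"] = rel * phi0
            else:
                d["phi0"] = phi0
                d["sigma_phi"] = rel * phi0
            return CodingRatioSpec.from_dict(d)

        frame = analysis.phase_diagram(
            spec_for, phi_grid, theta_grid, N=cfg.N, cm=cfg.cm,
            c_target=cfg.c_target, t_eval=cfg.t_eval, n_real=cfg.n_real,
            seed=cfg.seed, inhibition=cfg.inhibition,
        )

    elif cfg.experiment == "capacity":
        theta_grid = cfg.theta_grid or list(range(1, 61))
        P_grid = cfg.P_grid or [int(x) for x in np.geomspace(500, 16000, 10)]
        curve = analysis.capacity_sweep(
            spec, N=cfg.N, cm=cfg.cm, P_grid=P_grid, theta_grid=theta_grid,
            Q=cfg.Q, n_real=cfg.n_real, seed=cfg.seed, inhibition=cfg.inhibition,
        )
        frame = curve.to_frame()
        meta["Pc"] = curve.Pc
        meta["alpha"] = curve.alpha

    elif cfg.experiment == "scatter":
        sc = analysis.termination_scatter(
            spec, N=cfg.N, cm=cfg.cm, theta=cfg.theta, Q=cfg.Q,
            n_real=cfg.n_real, seed=cfg.seed, c_target=cfg.c_target, P=cfg.P,
            inhibition=cfg.inhibition,
        )
        frame = sc.to_frame()
        meta["frac_above"] = sc.frac_above
        meta["n_failed"] = sc.n_failed
        meta["n_completed"] = sc.n_completed

    elif cfg.experiment == "validate_network":
        # scaled-down cross-check of mean field vs binary network
        phi = sample_phi(spec, cfg.P, cfg.N, cfg.seed)
        p = meanfield.params_for_phi(phi, cfg.cm, cfg.theta)
        mf = meanfield.run_replay(phi, p, cfg.Q)
        pats = network.generate_patterns(phi.M, cfg.N, cfg.seed + 1)
        net = network.learn_willshaw(pats, cfg.cm, cfg.seed + 2, N=cfg.N)
        bn = network.simulate(net, cfg.Q, theta=cfg.theta)
        frame = pd.DataFrame(
            {
                "t": mf.t,
                "m_meanfield": mf.m,
                "n_meanfield": mf.n,
                "gamma_meanfield": mf.gamma,
                "m_network": bn.m,
                "n_network": bn.n,
                "gamma_network": bn.gamma,
            }
        )
        meta["varsigma_meanfield"] = p.varsigma
        meta["varsigma_network"] = net.potentiation_fraction
        meta["agree_success"] = bool(
            (mf.gamma[cfg.Q] > 0.5) == (bn.gamma[cfg.Q] > 0.5)
        )

    return _write(cfg, frame, meta)
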