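"""End-to-end orchestration: generate -> fit -> evolve -> optimize -> attribute.

A single :class:`RunConfig` (loadable from YAML) drives every stage; the
master seed derives one child seed per stochastic stage so a rerun with the
same config reproduces every artifact exactly.  Stage outputs are written
as CSV/JSON next to a machine-readable run report.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from petsorb import isotherms, kinetics, thermo
from petsorb.evolution import evolve
from petsorb.network import performance, save_surrogate
from petsorb.optimize import optimize_process
from petsorb.records import (
    build_feature_matrix,
    minmax_normalize,
    normalize_rows,
    one_hot,
    split_dataset,
    write_dataset,
)
from petsorb.shapley import exact_shapley
from petsorb.synth import (
    BASE_POINT,
    RANGES,
    TEMPERATURE_LEVELS,
    default_params,
    generate_dataset,
    isotherm_curve,
    kinetic_curve,
    kl_at_temperature,
)

ANTIBIOTICS = ("RIF", "RIX")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "petsorb_run"
    noise_cv: float = 0.05
    train_fraction: float = 0.7
    # DE topology search
    pop_size: int = 20
    generations: int = 30
    runs: int = 10
    # network training
    lr: float = 0.05
    max_epochs: int = 200
    patience: int = 20
    # process optimization
    opt_pop_size: int = 20
    opt_generations: int = 30
    antibiotics: tuple[str, ...] = ANTIBIOTICS

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_cv <= 0.2:
            raise ValueError(f"noise_cv={self.noise_cv} outside [0, 0.2]")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction={self.train_fraction} outside (0, 1)")
        for name, v in (
            ("pop_size", self.pop_size),
            ("generations", self.generations),
            ("runs", self.runs),
            ("max_epochs", self.max_epochs),
            ("opt_pop_size", self.opt_pop_size),
            ("opt_generations", self.opt_generations),
        ):
            if v < 1:
                raise ValueError(f"{name}={v} must be >= 1")
        if self.lr <= 0:
            raise ValueError(f"lr={self.lr} must be positive")
        for ab in self.antibiotics:
            one_hot(ab)
        for name, (lo, hi) in RANGES.items():
            if name == "pH" and not (0.0 <= lo <= hi <= 14.0):
                raise ValueError("pH range must lie within [0, 14]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "antibiotics" in raw:
            raw["antibiotics"] = tuple(raw["antibiotics"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["antibiotics"] = list(d["antibiotics"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _child_seeds(master: int, n: int) -> list[int]:
    rng = np.random.default_rng(master)
    return [int(rng.integers(2**31 - 1)) for _ in range(n)]


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order, writing artifacts under ``config.out_dir``.

    Returns the run report: a dict cross-linking every stage's key numbers
    and artifact paths, with the seeds that produced them.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = dict(
        zip(
            ("generate", "split", "evolve", "optimize", "curves"),
            _child_seeds(config.seed, 5),
        )
    )
    report: dict = {"config": asdict(config), "stage_seeds": seeds, "artifacts": {}}
    params = default_params(noise_cv=config.noise_cv)

    # stage 1: synthetic campaign
    dataset = generate_dataset(params=params, seed=seeds["generate"])
    write_dataset(dataset, out / "dataset.csv")
    report["artifacts"]["dataset"] = "dataset.csv"
    report["n_records"] = len(dataset)

    # stage 2: isotherm + kinetic fits per antibiotic, thermo from K_L(T)
    for ab in config.antibiotics:
        p = params[ab]
        c_eq, q = isotherm_curve(p, noise_cv=config.noise_cv, seed=seeds["curves"])
        fits = isotherms.fit_all_isotherms(c_eq, q)
        best = isotherms.select_best(fits)
        _dump(
            {"fits": [f.to_dict() for f in fits], "best_model": best.model},
            out / f"isotherms_{ab}.json",
        )

        t, q_t = kinetic_curve(p, noise_cv=config.noise_cv, seed=seeds["curves"] + 1)
        kin = {
            m: kinetics.fit_kinetic(t, q_t, model=m).to_dict() for m in ("PFO", "PSO")
        }
        kin["IPD"] = kinetics.ipd_two_region_fit(t, q_t).to_dict()
        _dump(kin, out / f"kinetics_{ab}.json")

        temps_K = np.array(TEMPERATURE_LEVELS) + 273.15
        K_T = [kl_at_temperature(p.K_L_ref, p.T_ref, T, p.dH) for T in temps_K]
        _dump(thermo.analyze(K_T, temps_K).to_dict(), out / f"thermo_{ab}.json")
        report["artifacts"][f"fits_{ab}"] = [
            f"isotherms_{ab}.json", f"kinetics_{ab}.json", f"thermo_{ab}.json"
        ]
        report[f"best_isotherm_{ab}"] = best.model

    # stage 3: surrogate neuroevolution
    train, test = split_dataset(dataset, config.train_fraction, seed=seeds["split"])
    fm_train = minmax_normalize(build_feature_matrix(train))
    fm_test_raw = build_feature_matrix(test)
    X_test = normalize_rows(fm_test_raw.X, fm_train.bounds)
    train_kwargs = {
        "lr": config.lr, "max_epochs": config.max_epochs, "patience": config.patience
    }
    model, history = evolve(
        fm_train.X, fm_train.y,
        pop_size=config.pop_size, generations=config.generations, runs=config.runs,
        seed=seeds["evolve"], bounds=fm_train.bounds, train_kwargs=train_kwargs,
    )
    perf = {
        "training": performance(model, fm_train.X, fm_train.y),
        "testing": performance(model, X_test, fm_test_raw.y),
    }
    _dump(
        {
            "best_topology": list(model.topology.hidden_layers),
            "run_seeds": history.run_seeds,
            "best_fitness_per_run": history.best_fitnesses,
            "best_fitness_per_generation": history.best_fitness_per_gen,
            "performance": perf,
        },
        out / "evolution.json",
    )
    save_surrogate(model, out / "surrogate.json")
    report["artifacts"]["evolution"] = "evolution.json"
    report["artifacts"]["surrogate"] = "surrogate.json"
    report["best_topology"] = list(model.topology.hidden_layers)
    report["performance"] = perf

    # stage 4/5: process optimization + Shapley attribution per antibiotic
    for ab in config.antibiotics:
        opt = optimize_process(
            model, antibiotic=ab, pop_size=config.opt_pop_size,
            generations=config.opt_generations, seed=seeds["optimize"],
        )
        _dump(opt.to_dict(), out / f"optimum_{ab}.json")
        report[f"optimum_{ab}"] = opt.to_dict()

        background = fm_train.X.mean(axis=0)
        hot = one_hot(ab)
        background[5], background[6] = float(hot[0]), float(hot[1])
        base_raw = np.array(
            [[BASE_POINT[k] for k in ("pH", "dose", "time", "c0", "temperature")]
             + [hot[0], hot[1]]]
        )
        instance = normalize_rows(base_raw, fm_train.bounds)[0]
        rep = exact_shapley(
            model.predict, background, instance,
            feature_names=("pH", "dose", "time", "c0", "temperature", "antibiotic"),
            groups=[[0], [1], [2], [3], [4], [5, 6]],
        )
        _dump(rep.to_dict(), out / f"attribution_{ab}.json")
        report[f"attribution_{ab}"] = rep.to_dict()

    report["elapsed_seconds"] = time.time() - t0
    _dump(report, out / "run_report.json")
    return report
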