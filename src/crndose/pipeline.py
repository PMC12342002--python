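"""End-to-end orchestration: physiological equilibrium -> mutations ->
drug stages -> profiles / dose scans / time courses, with plain CSV/JSON
outputs and a run manifest.

Configuration is a YAML/dict with keys::

    network: path to an interchange-format file (omit to use the built-in
             toy cascade)
    seed: int
    solver: {method: nlpc|ode, tol: float, restarts: int}
    mutations: [{protein, kind, level}]
    drugs: [{name, mechanism, targets, k_on, k_off, c0, degradation_rate,
             schedule_time_min}]
    scan: {drug: name, grid: [start, stop, num]}          # optional 1-D scan
    scan2: {drugA, gridA, drugB, gridB}                   # optional 2-D scan
    timecourse: {t_end_min, n_points, active_species, moiety}  # optional

Outputs are deterministic given the config and seed: CSV numbers are
written with ``repr`` and the manifest carries the config hash and seed so
every file can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conservation import find_conservation_laws
from .dynamics import AdministrationEvent, simulate, simulate_to_equilibrium
from .equilibrium import solve_equilibrium
from .metrics import (
    activated_fraction,
    delta_profile,
    dose_scan_1d,
    dose_scan_2d,
    geometric_index,
    top_variations,
)
from .network import Network, load_network
from .perturb import DrugSpec, MutationSpec, add_drug, compose_mutations, extend_state
from .synthetic import build_mapk_toy

__all__ = ["RunConfig", "run_pipeline", "plot_outputs", "load_config"]


@dataclass
class RunConfig:
    config: dict
    out_dir: Path
    seed: int = 0

    @property
    def solver(self) -> dict:
        return self.config.get("solver", {})


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _drug_spec(entry: dict) -> DrugSpec:
    return DrugSpec(
        name=entry["name"],
        mechanism=entry["mechanism"],
        targets=tuple(entry["targets"]),
        k_on=float(entry.get("k_on", 1e-3)),
        k_off=float(entry.get("k_off", 1e-2)),
        c0=float(entry.get("c0", 0.0)),
        degradation_rate=float(entry.get("degradation_rate", 0.0)),
        schedule_time=float(entry.get("schedule_time_min", 0.0)) * 60.0,
    )


def _write_equilibrium(path: Path, net: Network, x: np.ndarray) -> None:
    lines = ["species,x_e"]
    for name, v in zip(net.species_names, x):
        lines.append(f"{name},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: dict | RunConfig, out_dir: str | Path | None = None, seed: int | None = None) -> dict:
    """Execute the configured stages; returns a manifest dict (also written
    to ``manifest.json``)."""
    if isinstance(config, RunConfig):
        cfg, out, seed_val = config.config, config.out_dir, config.seed
    else:
        cfg, out, seed_val = config, Path(out_dir), (seed if seed is not None else config.get("seed", 0))
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    solver = dict(cfg.get("solver", {}))
    method = solver.pop("method", "nlpc")
    solver_kwargs = {k: v for k, v in solver.items() if k in ("tol", "restarts", "max_iter")}

    if cfg.get("network"):
        net = load_network(cfg["network"])
    else:
        net = build_mapk_toy()
    stages = []

    def solve(network, x0, stage):
        if method == "ode":
            res = simulate_to_equilibrium(network, x0)
        else:
            basis = find_conservation_laws(network)
            res = solve_equilibrium(network, basis, x0, seed=seed_val, **solver_kwargs)
        if not res.converged:
            raise RuntimeError(f"stage {stage}: equilibrium failed (residual {res.residual:.2e})")
        return res

    # stage 1: physiological equilibrium
    x0 = net.x0
    phys = solve(net, x0, "physiological")
    _write_equilibrium(out / "equilibrium_physiological.csv", net, phys.x_e)
    stages.append({"stage": "physiological", "residual": phys.residual})

    net_mut, x0_mut, x_tilde = net, x0, phys.x_e
    mutations = [
        MutationSpec(m["protein"], m["kind"], float(m.get("level", 0.0)))
        for m in cfg.get("mutations", [])
    ]
    if mutations:
        net_mut, x0_mut = compose_mutations(net, x0, mutations)
        mres = solve(net_mut, x0_mut, "mutated")
        x_tilde = mres.x_e
        _write_equilibrium(out / "equilibrium_mutated.csv", net_mut, x_tilde)
        prof = delta_profile(x_tilde, phys.x_e, net.species_names)
        prof.to_frame().to_csv(out / "delta_profile.csv", index=False)
        top_variations(x_tilde, phys.x_e, net.species_names).to_csv(
            out / "top_variations.csv", index=False
        )
        stages.append(
            {
                "stage": "mutated",
                "mutations": [f"{m.kind}:{m.protein}:{m.level}" for m in mutations],
                "residual": mres.residual,
                "G_delta": geometric_index(prof),
            }
        )

    drugs = {d["name"]: _drug_spec(d) for d in cfg.get("drugs", [])}
    loaded = [d for d in drugs.values() if d.c0 > 0]
    if loaded:
        aug, x_init, prev = net_mut, x_tilde, net_mut
        for spec in loaded:
            prev = aug
            aug = add_drug(aug, spec)
            x_init = extend_state(aug, prev, x_init, spec)
        dres = solve(aug, x_init, "drug_loaded")
        _write_equilibrium(out / "equilibrium_drug_loaded.csv", aug, dres.x_e)
        x_d = np.array([dres.x_e[aug.index(n)] for n in net.species_names])
        dprof = delta_profile(x_d, phys.x_e, net.species_names, role="drug_difference")
        dprof.to_frame().to_csv(out / "d_profile.csv", index=False)
        stages.append(
            {
                "stage": "drug_loaded",
                "drugs": [f"{d.name}:{d.c0}" for d in loaded],
                "residual": dres.residual,
                "G_d": geometric_index(dprof),
            }
        )

    if "scan" in cfg:
        sc = cfg["scan"]
        start, stop, num = sc["grid"]
        grid = np.linspace(float(start), float(stop), int(num))
        scan = dose_scan_1d(
            net_mut, x_tilde, phys.x_e, drugs[sc["drug"]], grid, seed=seed_val, **solver_kwargs
        )
        scan.to_frame().to_csv(out / "dose_scan.csv", index=False)
        (out / "dose_scan.json").write_text(
            json.dumps({"argmin": scan.argmin, "G_min": scan.G_min}, indent=1) + "\n"
        )
        stages.append({"stage": "dose_scan", "argmin": scan.argmin, "G_min": scan.G_min})

    if "scan2" in cfg:
        sc = cfg["scan2"]
        gA = np.linspace(*map(float, sc["gridA"][:2]), int(sc["gridA"][2]))
        gB = np.linspace(*map(float, sc["gridB"][:2]), int(sc["gridB"][2]))
        scan = dose_scan_2d(
            net_mut, x_tilde, phys.x_e, drugs[sc["drugA"]], drugs[sc["drugB"]],
            gA, gB, seed=seed_val, **solver_kwargs,
        )
        scan.to_frame().to_csv(out / "dose_scan_2d.csv", index=False)
        (out / "dose_scan_2d.json").write_text(
            json.dumps({"argmin": scan.argmin, "G_min": scan.G_min}, indent=1) + "\n"
        )
        stages.append({"stage": "dose_scan_2d", "argmin": scan.argmin, "G_min": scan.G_min})

    if "timecourse" in cfg:
        tc = cfg["timecourse"]
        t_end = float(tc.get("t_end_min", 1000.0)) * 60.0
        n_pts = int(tc.get("n_points", 200))
        aug, x_init, events = net_mut, x_tilde, []
        for spec in drugs.values():
            prev = aug
            aug = add_drug(aug, spec)
            x_init = extend_state(aug, prev, x_init, spec)
            if spec.schedule_time > 0:
                x_init[aug.index(spec.name)] = 0.0
                events.append(AdministrationEvent(spec.schedule_time, spec.name, spec.c0))
        t_grid = np.geomspace(1.0, t_end, n_pts)
        traj = simulate(aug, x_init, t_grid, events=events)
        traj.to_csv(out / "timecourse.csv")
        if "active_species" in tc:
            basis = find_conservation_laws(aug)
            frac = activated_fraction(traj, tc["active_species"], basis, tc["moiety"])
            pd.DataFrame({"time_min": traj.times / 60.0, "activated_fraction": frac}).to_csv(
                out / "activated_fraction.csv", index=False
            )
        stages.append({"stage": "timecourse", "t_end_s": t_end, "events": len(events)})

    manifest = {
        "version": __version__,
        "seed": seed_val,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float) + "\n")
    return manifest


def plot_outputs(out_dir: str | Path) -> list[Path]:
    """Render the figures a bundle supports: delta/d profiles, G(c) curve,
    G heatmap, activated fraction vs log-time (minutes)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    made = []

    def save(fig, name):
        path = out / name
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        made.append(path)

    for stem, role in (("delta_profile", "mutation_delta"), ("d_profile", "drug_difference")):
        f = out / f"{stem}.csv"
        if f.exists():
            df = pd.read_csv(f)
            fig, ax = plt.subplots(figsize=(7, 3))
            ax.plot(range(len(df)), df[role], marker=".", lw=0.8)
            ax.axhline(0, color="k", lw=0.5)
            ax.set_xlabel("species index")
            ax.set_ylabel("relative difference")
            save(fig, f"{stem}.png")
    f = out / "dose_scan.csv"
    if f.exists():
        df = pd.read_csv(f)
        fig, ax = plt.subplots()
        ax.plot(df["dose"], df["G"], marker="o")
        ax.set_xlabel("initial drug concentration (nM)")
        ax.set_ylabel("G")
        save(fig, "dose_scan.png")
    f = out / "dose_scan_2d.csv"
    if f.exists():
        df = pd.read_csv(f)
        piv = df.pivot(index="dose1", columns="dose2", values="G")
        fig, ax = plt.subplots()
        im = ax.pcolormesh(piv.columns, piv.index, piv.values, shading="nearest")
        fig.colorbar(im, ax=ax, label="G")
        ax.set_xlabel("drug B dose (nM)")
        ax.set_ylabel("drug A dose (nM)")
        save(fig, "dose_scan_2d.png")
    f = out / "activated_fraction.csv"
    if f.exists():
        df = pd.read_csv(f)
        fig, ax = plt.subplots()
        ax.semilogx(df["time_min"], df["activated_fraction"])
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activated fraction")
        save(fig, "activated_fraction.png")
    return made
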