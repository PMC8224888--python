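"""Config-driven end-to-end orchestration.

One "model" run mirrors the study protocol: n independent seeded ABF
trials of the chosen codon-model potential, per-trial and trial-averaged
probability/free-energy fields, binding scores for both (the two score
routes — ΔG from the trial-averaged P versus the mean of per-trial ΔG —
are distinct quantities and both are reported), all three 2-D
projections, the convergence series of the checkpointed fields, and the
bin-averaged bound structure. Every output is a declared plain-text
format plus a JSON manifest with seeds and file digests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abf import ABFParams, ABFRunResult, run_abf
from .dynamics import LangevinParams
from .fieldio import write_abf_state, write_field, write_trajectory
from .frames import generate_frames
from .grids import GridSpec, default_grid
from .landscape import (
    CheckpointSeries,
    average_probability,
    binding_scores,
    convergence_series,
    free_energy_from_probability,
    project,
    welch_t_test,
)
from .potentials import TripletPotential, WallParams
from .structure import BinSelector, average_structure, selection_report, write_structure
from .thermo import Thermo

__all__ = ["RunConfig", "run_model", "compare_models", "trial_seeds"]


@dataclass
class RunConfig:
    """Fully explicit configuration of one model run."""

    model: str = "AUG_like"
    n_trials: int = 5
    seed: int = 1
    outdir: str = "run_output"
    temperature: float = 310.0
    grid_lower: float = 4.0
    grid_upper: float = 9.0
    grid_width: float = 0.5
    wall_low: float = 3.0
    wall_high: float = 10.0
    wall_spring_pN_per_A: float = 10.0
    full_samples: int = 200
    n_steps: int = 400_000
    n_checkpoints: int = 10
    timestep: float = 0.01
    diffusion: float = 1.0
    record_stride: int = 100
    frame_stride: int = 20
    jitter_sigma: float = 0.05
    bound_bin_center: tuple = (4.5, 4.5, 4.5)
    potential_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bound_bin_center = tuple(
            float(c) for c in self.bound_bin_center
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["bound_bin_center"] = list(self.bound_bin_center)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    # -- derived objects ----------------------------------------------

    def thermo(self) -> Thermo:
        return Thermo(self.temperature)

    def grid(self) -> GridSpec:
        return GridSpec(
            (self.grid_lower,) * 3, (self.grid_upper,) * 3, self.grid_width
        )

    def walls(self) -> WallParams:
        return WallParams.from_pN_per_A(
            self.wall_spring_pN_per_A, self.thermo(),
            self.wall_low, self.wall_high,
        )

    def potential(self) -> TripletPotential:
        return TripletPotential.preset(self.model, **self.potential_overrides)

    def abf_params(self) -> ABFParams:
        walls = self.walls()
        return ABFParams(
            grid=self.grid(),
            full_samples=self.full_samples,
            checkpoint_stride=max(self.n_steps // self.n_checkpoints, 1),
            restraint_low=walls.low,
            restraint_high=walls.high,
            restraint_spring=walls.spring,
        )

    def dynamics(self) -> LangevinParams:
        return LangevinParams(
            timestep=self.timestep,
            diffusion=(self.diffusion,) * 3,
            temperature=self.temperature,
            n_steps=self.n_steps,
            record_stride=self.record_stride,
        )


def trial_seeds(master_seed: int, n_trials: int) -> list[int]:
    """Independent 31-bit trial seeds from one master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_trials)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_model(config: RunConfig) -> dict:
    """Run one model end to end; returns a summary dict (also on disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    thermo = config.thermo()
    abf_params = config.abf_params()
    dyn = config.dynamics()
    potential = config.potential()
    seeds = trial_seeds(config.seed, config.n_trials)

    results: list[ABFRunResult] = []
    score_rows = []
    for t, seed_t in enumerate(seeds):
        tdir = out / f"trial_{t:02d}"
        tdir.mkdir(exist_ok=True)
        res = run_abf(potential, dyn, abf_params, seed_t, thermo=thermo)
        results.append(res)
        write_trajectory(res.trajectory, tdir / "trajectory.tsv")
        write_abf_state(res.state, tdir / "abf_state.tsv")
        p_t = res.final_probability
        g_t = free_energy_from_probability(p_t, thermo)
        write_field(p_t, tdir / "probability_3d.tsv")
        write_field(g_t, tdir / "free_energy_3d.tsv")
        sc = binding_scores(g_t, p_t)
        score_rows.append(
            dict(model=config.model, trial=str(t), g_bound=sc.g_bound,
                 g_unbound=sc.g_unbound, dg_binding=sc.dg_binding,
                 units="kT")
        )

    avg_dir = out / "averaged"
    avg_dir.mkdir(exist_ok=True)
    p_avg = average_probability([r.final_probability for r in results])
    g_avg = free_energy_from_probability(p_avg, thermo)
    write_field(p_avg, avg_dir / "probability_3d.tsv")
    write_field(g_avg, avg_dir / "free_energy_3d.tsv")
    sc_avg = binding_scores(g_avg, p_avg)
    score_rows.append(
        dict(model=config.model, trial="averaged", g_bound=sc_avg.g_bound,
             g_unbound=sc_avg.g_unbound, dg_binding=sc_avg.dg_binding,
             units="kT")
    )
    scores = pd.DataFrame(score_rows)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)

    for pair, tag in (((1, 2), "d1d2"), ((2, 3), "d2d3"), ((1, 3), "d1d3")):
        g2, p2 = project(g_avg, p_avg, pair, thermo)
        write_field(g2, avg_dir / f"free_energy_{tag}.tsv")
        write_field(p2, avg_dir / f"probability_{tag}.tsv")

    conv = _convergence_table(results, thermo)
    conv.to_csv(out / "convergence.tsv", sep="\t", index=False)

    # bound-bin averaged structure from the first trial's trajectory
    jitter_seed = trial_seeds(config.seed + 2**20, 1)[0]
    ensemble = generate_frames(
        results[0].trajectory, stride=config.frame_stride,
        codon=_codon_of(config.model), jitter_sigma=config.jitter_sigma,
        seed=jitter_seed,
    )
    sel = BinSelector(tuple(config.bound_bin_center), config.grid_width)
    selection_report(ensemble, sel).to_csv(
        out / "selection_report.tsv", sep="\t", index=False
    )
    structure_rc = None
    try:
        avg = average_structure(ensemble, sel)
        write_structure(avg, out / "bound_structure.pdb")
        structure_rc = [float(x) for x in avg.rc]
    except ValueError:
        pass  # representative bin unpopulated in this run

    config.to_yaml(out / "config.yaml")
    manifest = {
        "version": __version__,
        "config_sha256": _sha256(out / "config.yaml"),
        "master_seed": config.seed,
        "trial_seeds": seeds,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "model": config.model,
        "dg_binding_averaged": sc_avg.dg_binding,
        "dg_binding_trials": [r["dg_binding"] for r in score_rows[:-1]],
        "final_L_3d": float(conv["L_3d"].iloc[-1]) if len(conv) else None,
        "structure_rc": structure_rc,
        "outdir": str(out),
    }


def _codon_of(model: str) -> str:
    return {"AUG_like": "AUG", "GUG_like": "GUG", "CUG_like": "CUG"}.get(
        model, "AUG"
    )


def _convergence_table(results, thermo) -> pd.DataFrame:
    """L series of the trial-averaged checkpoint stream, 3-D and projected."""
    n_chk = min(len(r.checkpoints) for r in results)
    if n_chk < 2:
        return pd.DataFrame(
            columns=["tau", "L_3d", "L_d1d2", "L_d2d3", "L_d1d3"]
        )
    taus = results[0].checkpoints.taus[:n_chk]
    avg_fields = [
        average_probability([r.checkpoints.fields[k] for r in results])
        for k in range(n_chk)
    ]
    series3 = CheckpointSeries(taus=list(taus), fields=avg_fields)
    table = {"tau": [t for t, _ in convergence_series(series3)],
             "L_3d": [l for _, l in convergence_series(series3)]}
    for pair, tag in (((1, 2), "d1d2"), ((2, 3), "d2d3"), ((1, 3), "d1d3")):
        proj_fields = []
        for p3 in avg_fields:
            g3 = free_energy_from_probability(p3, thermo)
            _, p2 = project(g3, p3, pair, thermo)
            proj_fields.append(p2)
        s2 = CheckpointSeries(taus=list(taus), fields=proj_fields)
        table[f"L_{tag}"] = [l for _, l in convergence_series(s2)]
    return pd.DataFrame(table)


def compare_models(run_dirs: list[str | Path]) -> pd.DataFrame:
    """Cross-model table: per-trial mean ± SEM of ΔG_binding, the
    averaged-field ΔG_binding, and pairwise Welch t/p on per-trial scores.
    """
    per_model: dict[str, pd.DataFrame] = {}
    for d in run_dirs:
        scores = pd.read_csv(Path(d) / "scores.tsv", sep="\t",
                             dtype={"trial": str})
        model = scores["model"].iloc[0]
        per_model[model] = scores
    rows = []
    for model, scores in per_model.items():
        trials = scores[scores["trial"] != "averaged"]["dg_binding"]
        if len(trials) == 0:
            raise ValueError(f"run for {model} has no per-trial scores")
        avg_row = scores[scores["trial"] == "averaged"]["dg_binding"]
        rows.append(
            dict(
                model=model,
                n_trials=len(trials),
                dg_mean_of_trials=trials.mean(),
                dg_sem_of_trials=(
                    trials.std(ddof=1) / np.sqrt(len(trials))
                    if len(trials) > 1 else np.nan
                ),
                dg_averaged_field=(
                    float(avg_row.iloc[0]) if len(avg_row) else np.nan
                ),
            )
        )
    table = pd.DataFrame(rows)
    for m1, m2 in combinations(sorted(per_model), 2):
        a = per_model[m1][per_model[m1]["trial"] != "averaged"]["dg_binding"]
        b = per_model[m2][per_model[m2]["trial"] != "averaged"]["dg_binding"]
        t, p = welch_t_test(a.to_numpy(), b.to_numpy())
        table.loc[table["model"] == m1, f"welch_t_vs_{m2}"] = t
        table.loc[table["model"] == m1, f"welch_p_vs_{m2}"] = p
    return table
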