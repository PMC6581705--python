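"""End-to-end orchestration of the comparative analysis on synthetic inputs.

A run config (YAML-compatible dict) names the stages to execute and their
parameters; `run_pipeline` executes them in dependency order (synth ->
torsion / affinity / ergm / cluster), writes every table artifact, and
records a manifest (inputs, parameters, seeds, versions, per-stage status
and wall time) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .affinity import (fit_affinity_model, affinity_score,
                       pair_support_vectors, sv_pair_angle_differences,
                       linearize_scores)
from .ergm import (ErgmModel, bayesian_bootstrap, fit_ergm_map,
                   rank_by_favorability, simulate_ergm)
from .markov import proximity_graph, select_k, transition_graph
from .properties import ABETA40_E22G, ABETA40_WT, ResidueProperties
from .psn import core_profile_contrast, edge_frequency_contrast
from .synthetic import (sample_conformations, sample_fibril_like,
                        simulate_trajectory, two_variant_spec)
from .torsion import angular_velocity, encode_circular

__all__ = ["default_config", "validate_config", "run_pipeline"]

STAGES = ("synth", "torsion", "affinity", "ergm", "cluster")


def default_config(seed: int = 0) -> dict:
    """A compact synthetic demo configuration exercising every stage."""
    return {
        "seed": seed,
        "synth": {
            "n_residues": 10,
            "n_conformations": 300,
            "trajectory_steps": 800,
            "shift": 0.35,
            "shift_residue": 6,
            "shift_kind": "psi",
        },
        "torsion": {},
        "affinity": {
            "folds": 5,
            "gamma_exponents": [-3, 0],
            "cost_exponents": [0],
            "n_fibril": 50,
        },
        "ergm": {
            "n_graphs": 60,
            "theta_a": {"edges": -2.5, "gwesp": 0.3},
            "theta_b": {"edges": -2.0, "gwesp": 0.6},
            "bootstrap": 12,
            "alpha": 0.05,
            "top": 5,
        },
        "cluster": {
            "k_min": 2,
            "k_max": 6,
            "reps": 3,
        },
    }


def validate_config(config: dict) -> list[str]:
    """Static validation; returns a list of issues (empty = valid)."""
    issues = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    if "seed" not in config:
        issues.append("missing required field: seed")
    if "synth" not in config:
        issues.append("missing required stage block: synth")
    synth = config.get("synth", {})
    if synth.get("n_residues", 10) < 2:
        issues.append("synth.n_residues out of range (need >= 2)")
    if synth.get("n_conformations", 1) < 1:
        issues.append("synth.n_conformations out of range (need >= 1)")
    shift = synth.get("shift", 0.0)
    if not -np.pi < shift <= np.pi:
        issues.append("synth.shift out of range (-pi, pi]")
    erg = config.get("ergm", {})
    alpha = erg.get("alpha", 0.05)
    if not 0 < alpha < 1:
        issues.append("ergm.alpha out of range (0, 1)")
    if erg.get("bootstrap", 2) < 2:
        issues.append("ergm.bootstrap out of range (need >= 2)")
    clu = config.get("cluster", {})
    if clu.get("k_min", 2) < 1 or clu.get("k_max", 6) < clu.get("k_min", 2):
        issues.append("cluster.k range invalid")
    for key in config:
        if key not in STAGES and key != "seed":
            issues.append(f"unknown config block: {key}")
    return issues


def _write_graph(g, path_prefix: Path, directed: bool) -> list[str]:
    """Attributed edge list + vertex table as TSV."""
    edge_rows, node_rows = [], []
    for u, v, data in g.edges(data=True):
        edge_rows.append({"from": u, "to": v, **data})
    for n, data in g.nodes(data=True):
        node_rows.append({"id": n, **data})
    ep = Path(f"{path_prefix}_edges.tsv")
    vp = Path(f"{path_prefix}_vertices.tsv")
    pd.DataFrame(edge_rows).to_csv(ep, sep="\t", index=False)
    pd.DataFrame(node_rows).to_csv(vp, sep="\t", index=False)
    return [str(ep), str(vp)]


def _seq_for(n_residues: int, variant_b: bool) -> str:
    seq = ABETA40_E22G if variant_b else ABETA40_WT
    if n_residues <= len(seq):
        return seq[:n_residues]
    reps = -(-n_residues // len(seq))
    return (seq * reps)[:n_residues]


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    ss = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(STAGES, ss.spawn(len(STAGES)))}
    manifest = {"config": config, "seed": seed, "version": __version__,
                "stage_seeds": stage_seeds, "stages": {}}

    state: dict = {}

    def run_stage(name, func):
        if name not in config:
            return
        if name != "synth" and manifest["stages"].get("synth", {}).get(
                "status") != "complete":
            manifest["stages"][name] = {"status": "skipped",
                                        "reason": "synth stage unavailable"}
            return
        t0 = time.perf_counter()
        try:
            outputs = func(config[name], stage_seeds[name])
            manifest["stages"][name] = {
                "status": "complete",
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": outputs,
            }
        except Exception as exc:  # noqa: BLE001 — recorded in the manifest
            manifest["stages"][name] = {
                "status": "failed",
                "seconds": round(time.perf_counter() - t0, 3),
                "error": f"{type(exc).__name__}: {exc}",
            }

    # --- synth ----------------------------------------------------------
    def stage_synth(params, sseed):
        spec = two_variant_spec(
            n_residues=params.get("n_residues", 10),
            shift=params.get("shift", 0.35),
            shift_residue=params.get("shift_residue", 6),
            shift_kind=params.get("shift_kind", "psi"),
            seed=sseed)
        n = params.get("n_conformations", 300)
        steps = params.get("trajectory_steps", 800)
        state["spec"] = spec
        state["conf"] = {v: sample_conformations(spec, v, n)
                         for v in spec.variants}
        state["traj"] = {v: simulate_trajectory(spec, v, steps)
                         for v in spec.variants}
        state["fibril"] = sample_fibril_like(spec, params.get("n_fibril", 50))
        outputs = []
        for v, cs in state["conf"].items():
            p = outdir / f"conformations_{v}.tsv"
            cs.to_tsv(p)
            outputs.append(str(p))
        for v, tr in state["traj"].items():
            p = outdir / f"trajectory_{v}.tsv"
            tr.to_tsv(p)
            outputs.append(str(p))
        p = outdir / "fibril_like.tsv"
        state["fibril"].to_tsv(p)
        outputs.append(str(p))
        return outputs

    # --- torsion --------------------------------------------------------
    def stage_torsion(params, sseed):
        outputs = []
        for v, cs in state["conf"].items():
            enc = encode_circular(cs)
            p = outdir / f"features_{v}.tsv"
            enc.to_tsv(p)
            outputs.append(str(p))
        rows = []
        for v, tr in state["traj"].items():
            vel = angular_velocity(tr)
            rows.append({"variant": v,
                         "mean_abs_velocity_rad_per_ps": float(np.abs(vel).mean())})
        p = outdir / "angular_velocity_summary.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        outputs.append(str(p))
        return outputs

    # --- affinity -------------------------------------------------------
    def stage_affinity(params, sseed):
        va, vb = state["spec"].variants
        enc_a = encode_circular(state["conf"][va])
        enc_b = encode_circular(state["conf"][vb])
        d = enc_a.matrix.shape[1]
        grid = {
            "gamma": [2.0 ** e / d for e in params.get("gamma_exponents", [-3, 0])],
            "cost": [2.0 ** e for e in params.get("cost_exponents", [0])],
        }
        model = fit_affinity_model(enc_a, enc_b, tuning_grid=grid,
                                   folds=params.get("folds", 5), seed=sseed)
        state["affinity_model"] = model
        outputs = []
        pairs = pair_support_vectors(model)
        table = sv_pair_angle_differences(pairs, model.angle_labels)
        p = outdir / "sv_angle_differences.tsv"
        table.to_csv(p, sep="\t", index=False)
        outputs.append(str(p))

        fib = sample_fibril_like(state["spec"], params.get("n_fibril", 50))
        enc_f = encode_circular(fib)
        scores = affinity_score(model, enc_f)
        p = outdir / "fibril_affinity_scores.tsv"
        pd.DataFrame({"conformation_id": enc_f.source_ids,
                      "score": scores}).to_csv(p, sep="\t", index=False)
        outputs.append(str(p))

        orrery = linearize_scores(scores, enc_f)
        p = outdir / "orrery_coefficients.tsv"
        orrery.to_frame().to_csv(p, sep="\t", index=False)
        outputs.append(str(p))
        state["cv_accuracy"] = model.cv_accuracy
        return outputs

    # --- ergm -----------------------------------------------------------
    def stage_ergm(params, sseed):
        n_res = state["spec"].n_residues
        props_a = ResidueProperties.from_sequence(_seq_for(n_res, False))
        props_b = ResidueProperties.from_sequence(_seq_for(n_res, True))
        model_a0 = ErgmModel.from_terms(**params.get("theta_a", {}))
        model_b0 = ErgmModel.from_terms(**params.get("theta_b", {}))
        n = params.get("n_graphs", 60)
        ens_a = simulate_ergm(model_a0, props_a, n, seed=sseed)
        ens_b = simulate_ergm(model_b0, props_b, n, seed=sseed + 1)
        for tag, ens in (("a", ens_a), ("b", ens_b)):
            for i, g in enumerate(ens):
                g.provenance = f"{tag}{i}"
        fit_a = fit_ergm_map(ens_a, props_a)
        fit_b = fit_ergm_map(ens_b, props_b)
        outputs = []
        m = params.get("bootstrap", 12)
        for tag, ens, props in (("a", ens_a, props_a), ("b", ens_b, props_b)):
            post = bayesian_bootstrap(ens, props, m=m, seed=sseed + 2)
            p = outdir / f"ergm_posterior_{tag}.tsv"
            post.summary.to_csv(p, sep="\t")
            outputs.append(str(p))
        alpha = params.get("alpha", 0.05)
        p = outdir / "core_contrast.tsv"
        core_profile_contrast(ens_a, ens_b, alpha).to_csv(p, sep="\t", index=False)
        outputs.append(str(p))
        p = outdir / "edge_contrast.tsv"
        edge_frequency_contrast(ens_a, ens_b, alpha).to_csv(p, sep="\t", index=False)
        outputs.append(str(p))
        fav_b, fav_a, table = rank_by_favorability(
            ens_a + ens_b, fit_a, fit_b, props_a, props_b,
            top=params.get("top", 5))
        p = outdir / "favorability.tsv"
        table.to_csv(p, sep="\t", index=False)
        outputs.append(str(p))
        state["favorability_top_b"] = [r.provenance for _, r in fav_b]
        return outputs

    # --- cluster --------------------------------------------------------
    def stage_cluster(params, sseed):
        trajs = list(state["traj"].values())
        res = select_k(trajs,
                       k_range=range(params.get("k_min", 2),
                                     params.get("k_max", 6) + 1),
                       reps=params.get("reps", 3), seed=sseed)
        outputs = []
        p = outdir / "tme_by_k.tsv"
        res.table.to_csv(p, sep="\t", index=False)
        outputs.append(str(p))
        p = outdir / "cluster_assignments.tsv"
        res.best_solution.assignment_frame().to_csv(p, sep="\t", index=False)
        outputs.append(str(p))
        for v, (model, C) in res.best_models.items():
            p = outdir / f"transition_counts_{v}.tsv"
            pd.DataFrame(model.Z).to_csv(p, sep="\t", index=False)
            outputs.append(str(p))
            p = outdir / f"transition_posterior_{v}.tsv"
            pd.DataFrame(C).to_csv(p, sep="\t", index=False)
            outputs.append(str(p))
            g = transition_graph(model, res.best_solution, v)
            outputs += _write_graph(g, outdir / f"transition_graph_{v}",
                                    directed=True)
        pg = proximity_graph(res.best_solution)
        outputs += _write_graph(pg, outdir / "proximity_graph", directed=False)
        state["selected_k"] = res.selected_k
        return outputs

    run_stage("synth", stage_synth)
    run_stage("torsion", stage_torsion)
    run_stage("affinity", stage_affinity)
    run_stage("ergm", stage_ergm)
    run_stage("cluster", stage_cluster)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
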