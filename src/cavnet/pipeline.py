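"""End-to-end experiment orchestration.

A *well* holds 4 cavities: one control plus up to three perturbed ones
(magnetic nanoparticles M, amyloid-beta, or the M-Abeta complex).  Each
cavity is recorded before and after the chemical application.  The
pipeline runs traces -> onsets -> sequences -> activity metrics -> drift
correction -> functional graphs -> communities -> topology for every
cavity and condition, writes every interface file, and emits a single
JSON summary that is reproducible from the config and its seeds.

Cavities either reference trace files (``traces: {before: ..., after: ...}``)
or are simulated from the generator spec in the config; the two modes can
be mixed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np

from . import io as cio
from .activity import (
    compare_conditions,
    difference_summary,
    drift_correct,
    summarize_activity,
)
from .communities import build_dendrogram, compare_partitions, normalized_jaccard_distance, select_threshold
from .connectivity import infer_functional_graph, significant_links, weight_differences
from .onsets import OnsetTrain, detect_onsets
from .sequences import coactivation_matrix, detect_sequences
from .synthetic import PerturbationSpec, apply_perturbation, generate_network, render_traces, simulate_activity
from .topology import topology_descriptors, topology_ratios

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "config_hash"]

CONDITIONS = ("before", "after")
ROLES = ("control", "M", "Abeta", "M-Abeta")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "duration": 1800.0,        # s per recording
    "frame_dt": 0.02,          # s
    "render_traces": False,    # True: render fluorescence and re-detect onsets
    "generator": {
        "n_clusters": 36,
        "n_communities": 3,
        "ignition_rate": 2.2,
        "participation": 0.7,
        "cross_participation": 0.03,
        "independent_rate": 0.1,
        "delay_scale": 0.030,
    },
    "analysis": {
        "amp_k": 3.0,
        "deriv_k": 2.0,
        "refractory": 0.5,
        "window": 0.2,
        "tau": 0.2,
        "n_surrogates": 500,
        "z_threshold": 1.95,
        "vi_step": 0.01,
        "noise_sd": 0.05,
    },
    "cavities": [
        {"name": "cav1", "role": "control"},
        {"name": "cav2", "role": "M",
         "perturbation": {"silenced_fraction": 0.05, "weaken_factor": 0.9}},
        {"name": "cav3", "role": "Abeta",
         "perturbation": {"silenced_fraction": 0.05, "weaken_factor": 0.8}},
        {"name": "cav4", "role": "M-Abeta",
         "perturbation": {"silenced_fraction": 0.3, "weaken_factor": 0.3}},
    ],
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    """Merge over defaults and check structure before any computation."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    if "seed" not in merged or merged["seed"] is None:
        raise ValueError("config must declare a seed")
    cavities = merged.get("cavities") or []
    if not cavities:
        raise ValueError("config declares no cavities")
    roles = [c.get("role") for c in cavities]
    for role in roles:
        if role not in ROLES:
            raise ValueError(f"unknown cavity role {role!r}; expected one of {ROLES}")
    if roles.count("control") != 1:
        raise ValueError("exactly one cavity must be the control")
    names = [c.get("name") for c in cavities]
    if len(set(names)) != len(names):
        raise ValueError("cavity names must be unique")
    for cav in cavities:
        traces = cav.get("traces")
        if traces is not None:
            for cond in CONDITIONS:
                if cond not in traces:
                    raise ValueError(f"cavity {cav['name']}: traces need 'before' and 'after'")
                if not Path(traces[cond]).exists():
                    raise FileNotFoundError(f"cavity {cav['name']}: missing {traces[cond]}")
    return merged


def _cavity_onsets(cav: dict, cfg: dict, seeds: dict) -> dict:
    """Onset trains per condition for one cavity, simulated or detected."""
    ana = cfg["analysis"]
    out: dict = {"onsets": {}, "duration": {}, "partition": None}
    if cav.get("traces"):
        for cond in CONDITIONS:
            reader = (
                cio.read_traces_hdf5
                if str(cav["traces"][cond]).endswith((".h5", ".hdf5"))
                else cio.read_traces_csv
            )
            rec = reader(cav["traces"][cond], condition=cond, cavity_role=cav["role"])
            out["onsets"][cond] = detect_onsets(
                rec, amp_k=ana["amp_k"], deriv_k=ana["deriv_k"], refractory=ana["refractory"]
            )
            out["duration"][cond] = rec.duration
        return out

    gen = cfg["generator"]
    network = generate_network(
        gen["n_clusters"], gen["n_communities"], seed=seeds["network"],
        ignition_rate=gen["ignition_rate"], participation=gen["participation"],
        cross_participation=gen["cross_participation"],
        independent_rate=gen["independent_rate"], delay_scale=gen["delay_scale"],
    )
    out["partition"] = network.community_of
    spec = PerturbationSpec(**cav.get("perturbation", {}))
    perturbed = apply_perturbation(network, spec, seed=seeds["perturbation"])
    for cond, net in (("before", network), ("after", perturbed)):
        onsets, _ = simulate_activity(net, cfg["duration"], seed=seeds[f"sim_{cond}"])
        if cfg.get("render_traces"):
            rec = render_traces(
                onsets, frame_dt=cfg["frame_dt"], noise_sd=ana["noise_sd"],
                seed=seeds[f"render_{cond}"], duration=cfg["duration"],
            )
            from .onsets import FluorescenceRecording

            trains = detect_onsets(
                FluorescenceRecording(rec.traces, cfg["frame_dt"], condition=cond),
                amp_k=ana["amp_k"], deriv_k=ana["deriv_k"], refractory=ana["refractory"],
            )
            # keep integer ids so downstream modules line up with ground truth
            trains = [
                OnsetTrain(i, t.onset_times) for i, t in enumerate(trains)
            ]
        else:
            trains = [OnsetTrain(i, t) for i, t in enumerate(onsets)]
        out["onsets"][cond] = trains
        out["duration"][cond] = cfg["duration"]
    return out


def _analyze_condition(trains, duration, cfg, seeds, cond) -> dict:
    ana = cfg["analysis"]
    sequences = detect_sequences(trains, window=ana["window"])
    summary = summarize_activity(trains, sequences, duration, condition=cond)
    return {"trains": trains, "sequences": sequences, "summary": summary}


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full experiment described by ``config``; write the report bundle.

    Returns the JSON-serializable summary (also written to
    ``out_dir/summary.json``).  Deterministic: rerunning with the same
    config yields a byte-identical summary.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ana = cfg["analysis"]
    chash = config_hash(cfg)

    cavity_seeds = {}
    for i, cav in enumerate(cfg["cavities"]):
        ss = np.random.SeedSequence(entropy=cfg["seed"], spawn_key=(i,))
        keys = ("network", "perturbation", "sim_before", "sim_after",
                "render_before", "render_after", "graph_before", "graph_after",
                "communities_before", "communities_after")
        children = ss.spawn(len(keys))
        cavity_seeds[cav["name"]] = {k: c for k, c in zip(keys, children)}

    results: dict = {}
    control_name = next(c["name"] for c in cfg["cavities"] if c["role"] == "control")
    for cav in cfg["cavities"]:
        seeds = cavity_seeds[cav["name"]]
        data = _cavity_onsets(cav, cfg, seeds)
        per_cond = {
            cond: _analyze_condition(
                data["onsets"][cond], data["duration"][cond], cfg, seeds, cond
            )
            for cond in CONDITIONS
        }
        results[cav["name"]] = {"cavity": cav, "conditions": per_cond, "data": data}

    control = results[control_name]["conditions"]
    summary: dict = {
        "config_hash": chash,
        "seed": cfg["seed"],
        "control": control_name,
        "cavities": {},
    }
    for name, res in results.items():
        cav = res["cavity"]
        cdir = out / name
        cdir.mkdir(exist_ok=True)
        before = res["conditions"]["before"]
        after = res["conditions"]["after"]
        corrected, drift = drift_correct(
            before["summary"], after["summary"],
            control["before"]["summary"], control["after"]["summary"],
        )
        diff = difference_summary(before["summary"], corrected)
        p_phi = (
            compare_conditions(before["summary"].phi, corrected.phi, test="t")
            if np.std(before["summary"].phi) > 0 or np.std(corrected.phi) > 0
            else 1.0
        )

        n = len(before["trains"])
        ids = [t.cluster_id for t in before["trains"]]
        seeds = cavity_seeds[name]
        graphs = {}
        for cond, part in (("before", before), ("after", after)):
            g = infer_functional_graph(
                part["sequences"], n, tau=ana["tau"],
                n_surrogates=ana["n_surrogates"],
                seed=int(seeds[f"graph_{cond}"].generate_state(1)[0] % (2**31)),
                cluster_ids=ids,
            )
            graphs[cond] = significant_links(g, ana["z_threshold"])
            cio.write_graph_tsv(cdir / f"graph_{cond}.tsv", graphs[cond])
            cio.write_graph_graphml(cdir / f"graph_{cond}.graphml", graphs[cond])
        wd = weight_differences(graphs["after"], graphs["before"])

        partitions = {}
        for cond, part in (("before", before), ("after", after)):
            X = coactivation_matrix(part["sequences"], ids)
            cio.write_coactivation_csv(cdir / f"coactivation_{cond}.csv", X)
            sim = normalized_jaccard_distance(
                X, n_surrogates=ana["n_surrogates"],
                seed=int(seeds[f"communities_{cond}"].generate_state(1)[0] % (2**31)),
            )
            dend = build_dendrogram(sim.D_norm)
            cio.write_dendrogram_csv(cdir / f"dendrogram_{cond}.csv", dend)
            try:
                _, partition = select_threshold(dend, step=ana["vi_step"])
            except ValueError:
                partition = None
            partitions[cond] = partition
            if partition is not None:
                cio.write_partition_json(cdir / f"partition_{cond}.json", partition)
            cio.write_onsets_tsv(cdir / f"onsets_{cond}.tsv", part["trains"])
            cio.write_sequences_jsonl(cdir / f"sequences_{cond}.jsonl", part["sequences"])

        topo = {
            cond: topology_descriptors(graphs[cond]) for cond in CONDITIONS
        }
        ratios = topology_ratios(topo["after"], topo["before"])

        community_report = (
            compare_partitions(partitions["before"], partitions["after"])
            if partitions["before"] is not None and partitions["after"] is not None
            else None
        )
        if community_report is not None:
            community_report = {
                k: v for k, v in community_report.items() if k != "mapping"
            }

        summary["cavities"][name] = {
            "role": cav["role"],
            "config_hash": chash,
            "seeds": {k: int(v.generate_state(1)[0] % (2**31)) for k, v in seeds.items()},
            "Phi_before": before["summary"].Phi,
            "Phi_after_corrected": corrected.Phi,
            "Phi_ratio": corrected.Phi / before["summary"].Phi
            if before["summary"].Phi > 0 else None,
            "Psi_before": before["summary"].Psi,
            "Psi_after_corrected": corrected.Psi,
            "Psi_ratio": corrected.Psi / before["summary"].Psi
            if before["summary"].Psi > 0 else None,
            "drift_r_phi": drift.r_phi,
            "drift_r_psi": drift.r_psi,
            "gamma": diff.gamma,
            "mu": diff.mu,
            "sigma": diff.sigma,
            "p_phi_t_test": p_phi,
            "wd_gamma": wd.gamma_wd,
            "wd_median": wd.median_wd,
            "topology_ratios": {k: (None if np.isnan(v) else v) for k, v in ratios.items()},
            "communities": community_report,
        }

    text = json.dumps(summary, indent=1, sort_keys=True, allow_nan=False, default=float)
    (out / "summary.json").write_text(text)
    cio.dump_config(out / "config_used.yaml", cfg)
    return summary
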