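"""End-to-end orchestration: simulate -> graph -> encode -> permute -> decode.

A :class:`PipelineConfig` names either a dataset directory or simulation
parameters, plus the split, lag filter, variant list, permutation and
decoder settings and a single root seed.  Every stochastic stage receives a
seed derived from the root seed by stable hashing of the stage name, so
stages are reproducible in isolation and the whole run is bit-reproducible
under a fixed config.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._utils import stage_seed
from . import __version__
from .dataset import FluorescenceDataset
from .decoding import decode_map, fit_coupled_decoder, fit_uncoupled_decoder
from .encoding import CORE_VARIANTS, ModelComparison, run_model_suite
from .network import FunctionalGraph, build_functional_graph
from .permutation import permutation_mse_change
from .simulate import (
    RunningParams,
    SyntheticDataset,
    generate_coupling,
    generate_protocol,
    generate_tuning,
    simulate_population,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "summarize_graph",
           "group_size_scaling", "simulate_from_config"]


@dataclass
class PipelineConfig:
    """Serializable configuration for a full analysis run."""

    data_dir: str | None = None
    simulation: dict = field(default_factory=dict)
    split_ratio: float = 0.7
    split_granularity: str = "block"
    max_lag: int = 17
    lag_filter: tuple[int, ...] = (0, 1)
    variants: tuple[str, ...] = CORE_VARIANTS
    permutation_schemes: tuple[str, ...] = ("weights", "edges")
    n_permutations: int = 200
    permutation_refit: bool = False
    decoder_shrinkage: float | None = None
    subsample_sizes: tuple[int, ...] = ()
    seed: int = 0
    out_dir: str = "funcgroups_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("lag_filter", "variants", "permutation_schemes", "subsample_sizes"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for k in ("lag_filter", "variants", "permutation_schemes", "subsample_sizes"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def save(self, path: str | pathlib.Path) -> None:
        pathlib.Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(pathlib.Path(path).read_text()))

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def simulate_from_config(sim: dict, seed: int) -> SyntheticDataset:
    """Build a synthetic dataset from a flat parameter dict.

    Recognized keys split into protocol (n_blocks, frame_rate_hz,
    presentation_frames, grey_frames), coupling (n_neurons, edge_density,
    lag_probabilities, positive_fraction, weight_range), tuning
    (tuned_fraction, concentration, baseline, stim_gain_range, run_gain)
    and simulation (running, calcium_tau_s, noise_sd, drive_noise_sd).
    """
    sim = dict(sim)
    n_neurons = int(sim.pop("n_neurons", 100))
    proto_keys = {"n_blocks", "frame_rate_hz", "presentation_frames", "grey_frames"}
    coup_keys = {"edge_density", "lag_probabilities", "positive_fraction", "weight_range"}
    tune_keys = {"tuned_fraction", "concentration", "baseline", "stim_gain_range", "run_gain"}
    sim_keys = {"calcium_tau_s", "noise_sd", "drive_noise_sd"}
    running = sim.pop("running", None)
    proto_kwargs = {k: sim.pop(k) for k in list(sim) if k in proto_keys}
    coup_kwargs = {k: sim.pop(k) for k in list(sim) if k in coup_keys}
    tune_kwargs = {k: sim.pop(k) for k in list(sim) if k in tune_keys}
    sim_kwargs = {k: sim.pop(k) for k in list(sim) if k in sim_keys}
    if "weight_range" in coup_kwargs:
        coup_kwargs["weight_range"] = tuple(coup_kwargs["weight_range"])
    if "stim_gain_range" in tune_kwargs:
        tune_kwargs["stim_gain_range"] = tuple(tune_kwargs["stim_gain_range"])
    if "lag_probabilities" in coup_kwargs:
        coup_kwargs["lag_probabilities"] = {
            int(k): float(v) for k, v in coup_kwargs["lag_probabilities"].items()
        }
    if sim:
        raise ValueError(f"unknown simulation keys: {sorted(sim)}")
    protocol = generate_protocol(seed=stage_seed(seed, "protocol"), **proto_kwargs)
    coupling = generate_coupling(n_neurons, seed=stage_seed(seed, "coupling"), **coup_kwargs)
    tuning = generate_tuning(n_neurons, seed=stage_seed(seed, "tuning"), **tune_kwargs)
    rp = RunningParams(**running) if running else None
    return simulate_population(
        protocol, coupling, tuning, running_params=rp,
        seed=stage_seed(seed, "simulate"), **sim_kwargs,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------
def summarize_graph(
    graph: FunctionalGraph, scaling_points: list[tuple[int, float, float]] | None = None
) -> dict:
    """Composition summary of a functional graph.

    Reports the weight and lag histograms, the percentage of bidirectional
    (lag-0) edges, the fraction of weights at lags 0-1, mean +/- sem
    functional group size, and the sign/lag composition of the strong edges.
    If `scaling_points` are given — (population size, mean total group size,
    mean strong-positive-bidirectional group size) triples — the two
    regression slopes of group size against population size are added.
    """
    e = graph.edges
    w = e["weight"].to_numpy()
    lags = e["lag"].to_numpy()
    strong = e[e["is_strong"]]
    sizes = graph.group_sizes()
    hist, edges_ = np.histogram(w, bins=40)
    out = {
        "n_neurons": graph.n_neurons,
        "n_edges": int(len(e)),
        "weight_hist_counts": hist.tolist(),
        "weight_hist_edges": edges_.tolist(),
        "lag_hist": {int(l): int((lags == l).sum()) for l in np.unique(lags)},
        "pct_bidirectional": 100.0 * float((e["direction"] == "bidirectional").mean()),
        "fraction_lag_0_1": float((lags <= 1).mean()),
        "mean_group_size": float(sizes.mean()),
        "sem_group_size": float(sizes.std(ddof=1) / np.sqrt(len(sizes))),
        "n_strong": int(len(strong)),
        "strong_threshold": graph.strong_threshold(),
        "strong_pct_positive": 100.0 * float((strong["weight"] > 0).mean()),
        "strong_pct_lag0": 100.0 * float((strong["lag"] == 0).mean()),
    }
    if scaling_points:
        out["group_size_scaling"] = group_size_scaling(scaling_points)
    return out


def group_size_scaling(points: list[tuple[int, float, float]]) -> dict:
    """Least-squares slopes of mean group size against population size,
    for all incoming edges and for the strong-positive-bidirectional subset."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two population sizes")
    slope_total = float(np.polyfit(pts[:, 0], pts[:, 1], 1)[0])
    slope_strong = float(np.polyfit(pts[:, 0], pts[:, 2], 1)[0])
    return {"slope_total": slope_total, "slope_strong_positive_bidirectional": slope_strong}


def _strong_positive_bidirectional_sizes(graph: FunctionalGraph) -> float:
    e = graph.edges
    sel = e[(e["is_strong"]) & (e["weight"] > 0) & (e["direction"] == "bidirectional")]
    counts = np.zeros(graph.n_neurons)
    for _, row in sel.iterrows():
        counts[int(row["neuron_a"])] += 1
        counts[int(row["neuron_b"])] += 1
    return float(counts.mean())


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------
@dataclass
class RunReport:
    """Per-stage summaries of a pipeline run; recomputable from artifacts."""

    config_hash: str
    version: str
    graph_summary: dict
    encoding_summary: list[dict]
    permutation_summaries: list[dict]
    decoding_summary: dict
    out_dir: str

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order, persisting each stage's artifact.

    Stage failures halt the run with the failing stage named; artifacts
    written before the failure are retained.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    stage = "load-data"
    try:
        if config.data_dir is not None:
            ds = FluorescenceDataset.load(config.data_dir)
        else:
            stage = "simulate"
            synth = simulate_from_config(config.simulation, config.seed)
            ds = synth.dataset
            ds.save(out / "dataset")

        stage = "graph"
        graph = build_functional_graph(
            ds, max_lag=config.max_lag, lag_filter=tuple(config.lag_filter)
        )
        graph.to_tsv(out / "graph.tsv")
        scaling = None
        if config.subsample_sizes:
            scaling = []
            rng = np.random.default_rng(stage_seed(config.seed, "subsample"))
            for size in config.subsample_sizes:
                keep = np.sort(rng.choice(ds.n_neurons, size=size, replace=False))
                sub = FluorescenceDataset(
                    traces=ds.traces[keep],
                    frame_rate_hz=ds.frame_rate_hz,
                    labels=ds.labels,
                    running_speed=ds.running_speed,
                    block_index=ds.block_index,
                    tuned=None if ds.tuned is None else ds.tuned[keep],
                )
                g = build_functional_graph(sub, max_lag=config.max_lag,
                                           lag_filter=tuple(config.lag_filter))
                scaling.append((size, float(g.group_sizes().mean()),
                                _strong_positive_bidirectional_sizes(g)))
        graph_summary = summarize_graph(graph, scaling_points=scaling)
        (out / "graph_summary.json").write_text(json.dumps(graph_summary, indent=1))

        stage = "encode"
        comparison = run_model_suite(
            ds, graph, variants=tuple(config.variants),
            split=(config.split_ratio, config.split_granularity),
            seed=stage_seed(config.seed, "split") if config.split_granularity != "block" else None,
        )
        comparison.results.to_csv(out / "encoding_results.csv", index=False)
        encoding_summary = comparison.summary().to_dict(orient="records")
        (out / "encoding_summary.json").write_text(json.dumps(encoding_summary, indent=1))

        stage = "permute"
        perm_summaries = []
        for scheme in config.permutation_schemes:
            res = permutation_mse_change(
                comparison, scheme=scheme, n_permutations=config.n_permutations,
                refit=config.permutation_refit,
                seed=stage_seed(config.seed, f"permute-{scheme}"),
            )
            (out / f"permutation_{scheme}.json").write_text(json.dumps(res.to_json()))
            perm_summaries.append(res.summary())

        stage = "decode"
        coupled = fit_coupled_decoder(ds, comparison, shrinkage=config.decoder_shrinkage)
        uncoupled = fit_uncoupled_decoder(ds, comparison.train_frames)
        res_c = decode_map(coupled)
        res_u = decode_map(uncoupled)
        decoding_summary = {
            "coupled_accuracy_pct": res_c.accuracy,
            "uncoupled_accuracy_pct": res_u.accuracy,
            "coupled_mi_bits": res_c.mutual_information,
            "uncoupled_mi_bits": res_u.mutual_information,
            "mi_gain_pct": 100.0
            * (res_c.mutual_information - res_u.mutual_information)
            / res_u.mutual_information
            if res_u.mutual_information > 0
            else float("nan"),
        }
        (out / "decode_coupled.json").write_text(json.dumps(res_c.to_json()))
        (out / "decode_uncoupled.json").write_text(json.dumps(res_u.to_json()))
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    report = RunReport(
        config_hash=config.hash(),
        version=__version__,
        graph_summary=graph_summary,
        encoding_summary=encoding_summary,
        permutation_summaries=perm_summaries,
        decoding_summary=decoding_summary,
        out_dir=str(out),
    )
    (out / "report.json").write_text(json.dumps(report.to_json(), indent=1))
    return report
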