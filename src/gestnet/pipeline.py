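"""Umbrella pipeline: simulate (or load) -> code -> build -> infer.

One call runs the whole analysis — segmentation and classification of the
gesture log, dyadic matrix construction, the six dyadic MRQAP models and
the node-level centrality model — and writes every intermediate artifact
plus a JSON report that records seeds, permutation counts and per-class
sequence tallies, enough to re-derive any reported number.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__
from .coding import code_events
from .io import write_json, write_matrix, write_table, read_table
from .mrqap import run_hypothesis_models
from .networks import build_networks
from .nodereg import run_centrality_model
from .synthetic import SyntheticConfig, simulate_dataset

logger = logging.getLogger("gestnet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Either three input paths (attrs/scans/events) or a synthetic block."""

    attrs_path: str | None = None
    scans_path: str | None = None
    events_path: str | None = None
    synthetic: SyntheticConfig | None = None
    strict_wait_window: bool = False
    drop_zero_exposure: bool = False
    n_perm: int = 2000
    seed: int = 0
    sex_age_coding: str = "separate"
    out_dir: str = "gestnet_out"

    def __post_init__(self) -> None:
        real = all(p is not None for p in (self.attrs_path, self.scans_path, self.events_path))
        some_real = any(p is not None for p in (self.attrs_path, self.scans_path, self.events_path))
        if self.synthetic is not None and some_real:
            raise ValueError("give either input paths or a synthetic block, not both")
        if self.synthetic is None and not real:
            raise ValueError("need attrs/scans/events paths or a synthetic block")
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        cfg = dict(cfg)
        syn = cfg.pop("synthetic", None)
        if syn is not None:
            allowed = {f.name for f in fields(SyntheticConfig)}
            bad = set(syn) - allowed
            if bad:
                raise ValueError(f"unknown synthetic config keys: {sorted(bad)}")
            for key in ("ages", "rapid_gap_range", "persistence_gap_range"):
                if key in syn and isinstance(syn[key], list):
                    syn[key] = tuple(syn[key])
            syn = SyntheticConfig(**syn)
        allowed = {f.name for f in fields(cls)}
        bad = set(cfg) - allowed
        if bad:
            raise ValueError(f"unknown pipeline config keys: {sorted(bad)}")
        return cls(synthetic=syn, **cfg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        logger.info("stage simulate: seed=%s", config.synthetic.seed)
        attrs, scans, events, _ = simulate_dataset(config.synthetic)
        write_table(attrs, out / "attributes.csv")
        write_table(scans, out / "scans.csv")
        write_table(events, out / "events.csv")
    else:
        logger.info("stage load: %s", config.events_path)
        attrs = read_table(config.attrs_path)
        scans = read_table(config.scans_path)
        events = read_table(config.events_path)

    try:
        sequences = code_events(events, strict_wait_window=config.strict_wait_window)
    except Exception as err:
        raise RuntimeError(f"stage 'code' failed: {err}") from err
    write_table(sequences, out / "sequences.csv")
    class_counts = sequences["cls"].value_counts().to_dict()
    logger.info("stage code: %d sequences %s", len(sequences), class_counts)

    try:
        networks, tallies = build_networks(scans, sequences, attrs)
    except Exception as err:
        raise RuntimeError(f"stage 'build' failed: {err}") from err
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for name, m in networks.items():
        write_matrix(m, net_dir / f"{name}.tsv")
    mask = ~tallies.zero_exposure_mask() if config.drop_zero_exposure else None

    try:
        dyadic = run_hypothesis_models(
            networks, n_perm=config.n_perm, seed=config.seed, mask=mask
        )
    except Exception as err:
        raise RuntimeError(f"stage 'mrqap' failed: {err}") from err
    logger.info("stage mrqap: %d models", len(dyadic))

    try:
        node_model = run_centrality_model(
            networks, attrs, n_perm=config.n_perm, seed=config.seed,
            sex_age_coding=config.sex_age_coding,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'nodereg' failed: {err}") from err

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_nodes": len(attrs),
        "n_dyads": len(attrs) * (len(attrs) - 1),
        "n_sequences": int(len(sequences)),
        "sequence_class_counts": {k: int(v) for k, v in class_counts.items()},
        "n_excluded_sequences": int(tallies.n_excluded),
        "strict_wait_window": config.strict_wait_window,
        "drop_zero_exposure": config.drop_zero_exposure,
        "dyadic_models": {k: r.to_dict() for k, r in dyadic.items()},
        "node_model": node_model.to_dict(),
    }
    write_json(report, out / "report.json")
    _write_text_report(report, out / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = [
        f"gestnet {report['version']}  seed={report['seed']} "
        f"perms={report['n_perm']} nodes={report['n_nodes']} dyads={report['n_dyads']}",
        f"sequences: {report['n_sequences']} {report['sequence_class_counts']} "
        f"(excluded: {report['n_excluded_sequences']})",
        "",
    ]
    for name, res in {**report["dyadic_models"], "node_level": report["node_model"]}.items():
        lines.append(f"== {name}: {res['outcome']} ~ ... "
                     f"(R^2 = {res['r_squared']:.3f}, {res['n_permutations']} perms)")
        for pred, b, p in zip(
            res["predictors"], res["standardized_coefficients"], res["p_values"]
        ):
            star = " *" if p < 0.05 else ""
            lines.append(f"   {pred:>34s}  beta_std = {b:+.3f}  p = {p:.3f}{star}")
        lines.append("")
    path.write_text("\n".join(lines))
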