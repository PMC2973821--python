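"""End-to-end pipeline: synth -> scan -> blockscan -> clusters -> quantgen,
plus batched forward simulations, driven by one YAML config.

Every stage writes TSV into the configured output directory and records the
file in a manifest with a sha256 checksum; identical config + seed gives an
identical manifest.  Stages run in dependency order and a failing stage
aborts everything downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import forward_sim, quantgen
from .divergence_scan import block_change_scan, scan
from .genotype_model import (
    LINE_HIGH,
    LINE_LOW,
    FixationClass,
    allele_frequencies,
    classify_fixation,
    concat_panels,
    read_panel,
    write_panel,
)
from .sweep_clusters import annotate_qtl_overlaps, cluster_fixed_snps, clusters_to_frame
from .synthetic_data import SweepSpec, SynthConfig, generate_dataset

log = logging.getLogger("divsel")

STAGE_ORDER = ("synth", "simulate", "scan", "blockscan", "clusters", "quantgen")


@dataclass
class RunConfig:
    """Parsed pipeline configuration: global seed, output dir, stage blocks."""

    seed: int = 0
    out_dir: str = "divsel_out"
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        stages = {k: v for k, v in raw.items() if k in STAGE_ORDER and v is not None}
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "divsel_out")),
            stages=stages,
        )


def default_demo_config(out_dir: str = "divsel_out", seed: int = 0) -> RunConfig:
    """A small end-to-end demo: 5,000 SNPs, three planted sweeps."""
    return RunConfig.from_dict(
        {
            "seed": seed,
            "out_dir": out_dir,
            "synth": {
                "n_snps": 5000,
                "sweeps": [
                    {"chromosome": "1", "center_bp": 5_000_000, "half_width_bp": 200_000,
                     "line_favoured": "HIGH", "fixation_generation": 40},
                    {"chromosome": "2", "center_bp": 8_000_000, "half_width_bp": 150_000,
                     "line_favoured": "LOW", "fixation_generation": 40},
                    {"chromosome": "24", "center_bp": 3_000_000, "half_width_bp": 120_000,
                     "line_favoured": "HIGH", "fixation_generation": 50},
                ],
            },
            "scan": {"generation": 40},
            "blockscan": {"line": "HIGH", "generations": [40, 50]},
            "clusters": {"generation": 40, "max_gap_bp": 1_000_000, "min_snps": 2},
        }
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and return the artifact manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: list[str] = []
    manifest: dict[str, Any] = {"seed": config.seed, "stages": list(config.stages)}
    panel = marker_map = None

    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        params = dict(config.stages[stage])
        log.info("stage %s: %s", stage, params)
        try:
            if stage == "synth":
                panel, marker_map, paths = _run_synth(params, config)
                artifacts += paths
            elif stage == "simulate":
                artifacts += _run_simulate(params, config)
            else:
                if panel is None:
                    panel_path = params.pop("panel", None)
                    if panel_path is None:
                        raise ValueError(f"stage {stage} needs a panel (run synth or set 'panel')")
                    panel, marker_map = read_panel(panel_path + ".ped", panel_path + ".map")
                if stage == "scan":
                    artifacts += _run_scan(panel, params, config)
                elif stage == "blockscan":
                    artifacts += _run_blockscan(panel, marker_map, params, config)
                elif stage == "clusters":
                    artifacts += _run_clusters(panel, marker_map, params, config)
                elif stage == "quantgen":
                    artifacts += _run_quantgen(params, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["artifacts"] = [
        {"path": os.path.relpath(p, config.out_dir), "sha256": _sha256(p)}
        for p in artifacts
    ]
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_synth(params: dict[str, Any], config: RunConfig):
    sweeps = [SweepSpec(**sw) for sw in params.pop("sweeps", [])]
    sample_sizes = params.pop("sample_sizes", None)
    kwargs = dict(params)
    if sample_sizes is not None:
        kwargs["sample_sizes"] = {
            (line, int(gen)): int(n)
            for (line, gen), n in (
                ((k.split(":")[0], k.split(":")[1]), v) for k, v in sample_sizes.items()
            )
        }
    synth_cfg = SynthConfig(sweeps=sweeps, seed=config.seed, **kwargs)
    ds = generate_dataset(synth_cfg)
    panel = concat_panels([ds.panels[g] for g in sorted(ds.panels)])
    prefix = os.path.join(config.out_dir, "synth")
    paths = list(write_panel(panel, ds.marker_map, prefix).values())
    paths.append(_write_tsv(ds.truth, os.path.join(config.out_dir, "ground_truth.tsv")))
    return panel, ds.marker_map, paths


def _run_simulate(params: dict[str, Any], config: RunConfig) -> list[str]:
    scheme = forward_sim.BreedingScheme(**params.get("scheme", {}))
    n_reps = int(params.get("replicates", 1000))
    max_gen = int(params.get("generations", 50))
    rows = []
    rng = np.random.default_rng(config.seed)
    for sc in params.get("scenarios", []):
        sel = forward_sim.SelectionParams(
            s_male=float(sc.get("s_male", 0.0)),
            s_female=float(sc.get("s_female", 0.0)),
            h=float(sc.get("h", 0.5)),
        )
        out = forward_sim.run_replicates(
            forward_sim.HaplotypeFreqs(str(sc.get("hap_code", "4003"))),
            scheme, sel, float(sc.get("r", 0.05)), n_reps, max_gen, rng,
        )
        row = out.summary()
        row.insert(0, "scenario", sc.get("name", "unnamed"))
        row.insert(1, "s_male", sel.s_male)
        row.insert(2, "s_female", sel.s_female)
        rows.append(row)
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return [_write_tsv(table, os.path.join(config.out_dir, "simulations.tsv"))]


def _run_scan(panel, params: dict[str, Any], config: RunConfig) -> list[str]:
    gen = params.get("generation")
    res = scan(
        panel,
        (LINE_HIGH, gen),
        (LINE_LOW, gen),
        alphas=tuple(params.get("alphas", (0.05, 0.001))),
        include_fisher=bool(params.get("fisher", False)),
    )
    return [_write_tsv(res.table, os.path.join(config.out_dir, "scan.tsv"))]


def _run_blockscan(panel, marker_map, params: dict[str, Any], config: RunConfig) -> list[str]:
    g1, g2 = params.get("generations", (40, 50))
    bs = block_change_scan(
        panel, marker_map, params.get("line", LINE_HIGH), int(g1), int(g2),
        block_size=int(params.get("block_size", 5)),
        percentile=float(params.get("percentile", 95)),
        window_blocks=int(params.get("window_blocks", 20)),
        p_threshold=float(params.get("p_threshold", 1e-5)),
    )
    return [
        _write_tsv(bs.blocks, os.path.join(config.out_dir, "blocks.tsv")),
        _write_tsv(bs.windows, os.path.join(config.out_dir, "block_windows.tsv")),
    ]


def _run_clusters(panel, marker_map, params: dict[str, Any], config: RunConfig) -> list[str]:
    gen = params.get("generation")
    fh = allele_frequencies(panel, line=LINE_HIGH, generation=gen)
    fl = allele_frequencies(panel, line=LINE_LOW, generation=gen)
    diff = classify_fixation(fh, fl) == FixationClass.DIFF
    clusters, summary = cluster_fixed_snps(
        diff, marker_map,
        max_gap_bp=int(params.get("max_gap_bp", 1_000_000)),
        min_snps=int(params.get("min_snps", 2)),
    )
    if params.get("qtl_bed"):
        clusters = annotate_qtl_overlaps(clusters, params["qtl_bed"])
    table = clusters_to_frame(clusters)
    paths = [_write_tsv(table, os.path.join(config.out_dir, "clusters.tsv"))]
    summary_path = os.path.join(config.out_dir, "clusters_summary.json")
    with open(summary_path, "w") as fh_:
        json.dump(summary, fh_, indent=2, sort_keys=True)
    paths.append(summary_path)
    return paths


def _run_quantgen(params: dict[str, Any], config: RunConfig) -> list[str]:
    rows = []
    for oj in params.get("otto_jones", []):
        res = quantgen.otto_jones(
            quantgen.OttoJonesInput(
                D=float(oj["D"]), M=float(oj["M"]),
                a_min=float(oj["a_min"]), n_d=int(oj["n_d"]),
            )
        )
        rows.append(
            {"quantity": f"otto_jones:{oj.get('trait', '?')}",
             "value": res.n_loci, "detail": f"T={res.threshold_T:.4g} raw={res.n_loci_raw:.4g}"}
        )
    if "ne_parents" in params:
        nm, nf = params["ne_parents"]
        rows.append({"quantity": "ne_from_parents", "value": quantgen.ne_from_parents(nm, nf), "detail": f"{nm}M/{nf}F"})
    if "ne_segments" in params:
        seg = quantgen.NeSegments(
            segments=tuple((int(n), float(ne)) for n, ne in params["ne_segments"]["segments"]),
            total_generations=float(params["ne_segments"]["total_generations"]),
        )
        rows.append({"quantity": "harmonic_ne", "value": quantgen.harmonic_ne(seg), "detail": ""})
    table = pd.DataFrame(rows)
    return [_write_tsv(table, os.path.join(config.out_dir, "quantgen.tsv"))]
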