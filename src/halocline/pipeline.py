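"""End-to-end orchestration: rarefy -> diversity -> beta diversity -> core
taxa -> neutral model -> stochasticity ratio -> niche breadth -> network,
driven by a YAML config, with a machine-readable JSON report."""

from __future__ import annotations

import json
import logging
import traceback
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import betadiv, core_taxa, diversity, ncm
from . import network as net_mod
from .nst import niche_breadth, nst as run_nst
from .tables import (
    CountTable,
    SampleMetadata,
    aggregate_taxonomy,
    rarefy,
    read_count_table,
    read_metadata,
    read_taxonomy,
    to_relative,
    write_count_table,
)

logger = logging.getLogger("halocline")

_KNOWN_KEYS = {
    "counts", "metadata", "taxonomy", "output_dir", "depth", "seed",
    "diversity", "betadiv", "core", "ncm", "nst", "network",
}
_STAGES = (
    "rarefy", "diversity", "betadiv", "core", "ncm", "nst",
    "niche_breadth", "network",
)


@dataclass
class PipelineConfig:
    counts: str
    metadata: str
    output_dir: str
    taxonomy: str | None = None
    depth: int | str = "min"           # "min" or an explicit integer
    seed: int = 0
    diversity: dict = field(default_factory=dict)
    betadiv: dict = field(default_factory=dict)
    core: dict = field(default_factory=dict)
    ncm: dict = field(default_factory=dict)
    nst: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("counts", "metadata", "output_dir"):
            if key not in raw:
                raise ValueError(f"config missing required key {key!r}")
        cfg = cls(**raw)
        for key in ("counts", "metadata", "taxonomy"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        if not isinstance(cfg.seed, int):
            raise ValueError("seed must be an integer")
        if cfg.depth != "min" and not isinstance(cfg.depth, int):
            raise ValueError("depth must be 'min' or an integer")
        return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order and write a JSON report.

    Stage failures downstream of rarefaction are recorded (with stack
    context) without aborting the remaining independent stages.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_count_table(config.counts)
    meta = read_metadata(config.metadata)
    tax = read_taxonomy(config.taxonomy) if config.taxonomy else None
    report: dict = {
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "stages": {},
    }

    depth = (
        int(table.sample_totals().min()) if config.depth == "min" else config.depth
    )
    table = rarefy(table, depth, stage_seed(config.seed, "rarefy"))
    report["stages"]["rarefy"] = {
        "params": {"depth": depth, "seed": stage_seed(config.seed, "rarefy")},
        "n_samples": len(table.sample_ids),
        "grand_total": int(table.counts.sum()),
    }
    write_count_table(table, out / "rarefied.tsv")
    groups = meta.groups_for(table.sample_ids)

    def _stage(name, fn):
        seed = stage_seed(config.seed, name)
        try:
            block = fn(seed)
            block.setdefault("params", {})["seed"] = seed
            report["stages"][name] = block
        except Exception as e:  # optional stage: log, record, continue
            logger.error("stage %s failed: %s", name, e)
            report["stages"][name] = {
                "error": str(e),
                "traceback": traceback.format_exc(),
            }

    def s_diversity(seed):
        params = dict(config.diversity)
        alpha = diversity.alpha_diversity(table, **params)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        return {"params": params, "mean_shannon": float(alpha["shannon"].mean())}

    def s_betadiv(seed):
        params = {"n_perm": 999, **config.betadiv}
        dm = betadiv.bray_curtis(table)
        pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
            out / "bray_curtis.tsv", sep="\t"
        )
        ord_res = betadiv.pcoa(dm)
        coords = pd.DataFrame(
            ord_res.coordinates,
            index=dm.sample_ids,
            columns=[f"PC{i + 1}" for i in range(ord_res.coordinates.shape[1])],
        )
        coords.to_csv(out / "pcoa.tsv", sep="\t")
        perm = betadiv.permanova(dm, groups, n_perm=params["n_perm"], seed=seed)
        (out / "upgma.nwk").write_text(betadiv.upgma(dm) + "\n")
        return {
            "params": params,
            "permanova": {
                "pseudo_F": perm.pseudo_F, "R2": perm.R2, "p_value": perm.p_value,
            },
            "pc1_pc2_explained": float(ord_res.proportion_explained[:2].sum()),
        }

    def s_core(seed):
        params = {"occurrence_min": 0.8, "mean_ra_min": 0.001, **config.core}
        cores = core_taxa.core_by_group(table, meta, **params)
        rows = []
        for g, cs in cores.items():
            cs.members.assign(group=g).to_csv(out / f"core_{g}.tsv", sep="\t")
            rows.append({
                "group": g,
                "n_core": len(cs.members),
                "core_fraction_of_reads": cs.core_fraction_of_reads,
            })
        shared = sorted(core_taxa.shared_core(cores.values())) if len(cores) > 1 else []
        (out / "shared_core.txt").write_text("\n".join(shared) + "\n")
        return {"params": params, "groups": rows, "n_shared": len(shared)}

    def s_ncm(seed):
        fits = {}
        for g in pd.unique(groups):
            sub = table.select_samples(
                [s for s, lab in zip(table.sample_ids, groups) if lab == g]
            )
            fit = ncm.fit_ncm(sub)
            fit.curve.to_csv(out / f"ncm_curve_{g}.tsv", sep="\t")
            fits[str(g)] = {
                "Nm": fit.Nm, "m": fit.m, "N": fit.N, "d": fit.d,
                "r_squared": fit.r_squared,
                "partition": fit.partition_counts,
            }
        return {"params": {}, "fits": fits}

    def s_nst(seed):
        params = {"metric": "bray-curtis", "n_draws": 1000, **config.nst}
        results = run_nst(table, groups, seed=seed, **params)
        pairwise = pd.concat(
            [r.pairwise.assign(group=g) for g, r in results.items()],
            ignore_index=True,
        )
        pairwise.to_csv(out / "nst_pairwise.tsv", sep="\t", index=False)
        return {
            "params": params,
            "groups": {
                g: {"nst": r.nst, "classification": r.classification}
                for g, r in results.items()
            },
        }

    def s_breadth(seed):
        nb = niche_breadth(table)
        nb.breadth.to_frame().to_csv(out / "niche_breadth_taxa.tsv", sep="\t")
        nb.bcom.to_frame().to_csv(out / "niche_breadth_bcom.tsv", sep="\t")
        lab = pd.Series(groups, index=table.sample_ids)
        group_bcom = nb.bcom.groupby(lab).mean()
        return {"params": {}, "group_bcom": group_bcom.to_dict()}

    def s_network(seed):
        params = {"rank": "genus", **config.network}
        rank = params.pop("rank")
        t = aggregate_taxonomy(table, tax, rank) if tax is not None else table
        cfg = net_mod.NetworkConfig(seed=seed, **params)
        net = net_mod.build_network(t, cfg)
        net.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        topo = net_mod.topology(net)
        (out / "network_topology.json").write_text(json.dumps(topo, indent=2))
        return {"params": {**params, "rank": rank}, "topology": topo}

    _stage("diversity", s_diversity)
    _stage("betadiv", s_betadiv)
    _stage("core", s_core)
    _stage("ncm", s_ncm)
    _stage("nst", s_nst)
    _stage("niche_breadth", s_breadth)
    _stage("network", s_network)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
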