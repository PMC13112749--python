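"""End-to-end orchestration: simulate -> classify -> call cells -> matrices
-> tracks -> melting -> phasing, from a single YAML configuration.

Per-stage seeds are derived from the global seed by stable hashing, so a
stage re-run in isolation reproduces its in-pipeline output; re-running
the whole pipeline with the same config yields byte-identical tables.
"""

from __future__ import annotations

import copy
import difflib
import json
import time
import warnings
import zlib
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .cell_calling import assign_species, collision_rate, find_knees, rank_barcodes
from .classify import FragmentMap, cell_qc, classify_pairs, deduplicate
from .matrix import bin_contacts, downsample_per_cell, ice_balance
from .melting import (RegionOfInterest, cluster_states, depth_guard,
                      melting_score, per_cell_insulation_matrix)
from .phasing import RepliTrack, group_compare_trans_cis, haploid_score, repli_score
from .simulate import ArtifactFractions, SimConfig, simulate_cells
from .tracks import (BoundaryCallParams, InsulationParams, call_boundaries,
                     compartment_eigenvector, insulation_scores)

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "schicmelt_out",
    "write_pairs": False,
    "stages": {
        "simulate": True, "classify": True, "callcells": True,
        "tracks": True, "melting": True, "phasing": True,
    },
    "simulate": {
        "n_cells": {"alpha": 100, "beta": 100},
        "doublet_rate": 0.06,
        "n_background_barcodes": 500,
        "duplicate_rate": 0.15,
        "mito_fp_rate": 0.01,
        "trans_rate": 0.2,
        "decay_exponent": 1.0,
        "mean_pairs_per_cell": 6800,
        "melting_fraction": 0.3,
        "artifact_fractions": {"dangling_end": 0.18, "self_circle": 0.08,
                               "religation": 0.12, "dumped": 0.12},
    },
    "classify": {"min_mapq": 10},
    "callcells": {"sensitivity": 1.0, "contrast": 5.0, "species_threshold": 0.89},
    "tracks": {"bin_size": 50_000, "min_depth": 200_000, "max_depth": 750_000,
               "step": 50_000, "delta": 0.01, "balance": True},
    "melting": {"roi": None, "equal_depth": 2500, "depth_guard": 1250},
    "phasing": {"haploid_threshold": 1.5},
}

_UNITS = {"k": 1e3, "m": 1e6, "g": 1e9}


class ConfigError(ValueError):
    pass


def _expand_units(value):
    if isinstance(value, str):
        v = value.strip().lower().replace(",", "").replace("_", "")
        if v and v[-1] in _UNITS and v[:-1].replace(".", "", 1).isdigit():
            num = float(v[:-1]) * _UNITS[v[-1]]
            return int(num) if num == int(num) else num
    return value


def _merge(defaults, user, path=""):
    if not isinstance(user, dict):
        raise ConfigError(f"section {path or '<root>'} must be a mapping")
    out = copy.deepcopy(defaults)
    free_form = path.endswith("n_cells")   # arbitrary species names allowed
    for key, val in user.items():
        if key not in defaults and not free_form:
            near = difflib.get_close_matches(str(key), list(defaults), n=1)
            hint = f"; did you mean {near[0]!r}?" if near else ""
            raise ConfigError(f"unknown key {path + str(key)!r}{hint}")
        if isinstance(defaults.get(key), dict) and key != "n_cells":
            out[key] = _merge(defaults[key], val, f"{path}{key}.")
        else:
            out[key] = _expand_units(val) if not isinstance(val, dict) else {
                k: _expand_units(v) for k, v in val.items()}
    return out


def validate_config(source) -> dict:
    """Load, validate and normalize a pipeline config (path, YAML string or
    dict).  Unknown keys are itemized with the nearest valid name; unit
    suffixes (200k, 1M) are expanded; defaults filled."""
    if isinstance(source, dict):
        raw = source
    else:
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
    cfg = _merge(DEFAULTS, raw)
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 0x9E3779B1)) % (2**31)


def run_pipeline(config, outdir=None) -> dict:
    """Execute all enabled stages; returns the run report (also written to
    ``outdir/run_report.json`` beside the resolved-config echo)."""
    cfg = validate_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    report: dict = {"stages": {}, "parameters": cfg, "warnings": []}
    t_all = time.time()

    def log_stage(name, t0, **counts):
        report["stages"][name] = {"seconds": round(time.time() - t0, 2), **counts}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        state = _run_stages(cfg, out, log_stage)
    report["warnings"] = sorted({str(w.message) for w in caught})
    report["total_seconds"] = round(time.time() - t_all, 2)
    if "qc" in state:
        qc = state["qc"]
        report["qc_summary"] = {
            "n_barcodes": int(len(qc)),
            "median_valid_pair_ratio": float(qc["valid_pair_ratio"].median()),
            "median_reported_pair_ratio": float(qc["reported_pair_ratio"].median()),
            "median_dup_rate": float(qc["dup_rate"].median()),
            "median_log2_cis_trans": float(qc["log2_cis_trans"].median()),
            "total_pairs": int(qc["total_pairs"].sum()),
            "unique_valid_pairs": int(qc["unique_valid_pairs"].sum()),
        }
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _sim_config(sec: dict, seed: int) -> SimConfig:
    af = ArtifactFractions(**sec["artifact_fractions"])
    kwargs = {k: v for k, v in sec.items() if k != "artifact_fractions"}
    kwargs["n_cells"] = {str(k): int(v) for k, v in sec["n_cells"].items()}
    return SimConfig(artifact_fractions=af, rng_seed=seed, **kwargs)


def _run_stages(cfg: dict, out: Path, log_stage) -> dict:
    stages = cfg["stages"]
    state: dict = {}

    if stages["simulate"]:
        t0 = time.time()
        sim = simulate_cells(config=_sim_config(cfg["simulate"],
                                                stage_seed(cfg["seed"], "simulate")))
        state["sim"] = sim
        pio.write_table(sim.truth, out / "ground_truth.tsv")
        if cfg["write_pairs"]:
            pio.write_pairs(sim.pairs, out / "pairs.tsv")
        log_stage("simulate", t0, pairs=len(sim.pairs), barcodes=len(sim.truth))
        pairs = sim.pairs
        genomes = sim.genomes
    else:
        raise ConfigError("external pairs input requires stages.simulate "
                          "or a pairs path (not configured)")

    chrom_lengths, cuts, chrom_species = {}, {}, {}
    for tag, g in genomes.items():
        for c in g.chromosomes:
            chrom_lengths[c.name] = c.length
            cuts[c.name] = g.cut_sites[c.name]
            chrom_species[c.name] = tag
    fragmap = FragmentMap(cuts, chrom_lengths)
    mito = {g.mito_chrom for g in genomes.values()}

    if stages["classify"]:
        t0 = time.time()
        cl = classify_pairs(pairs, fragmap, min_mapq=cfg["classify"]["min_mapq"])
        cl = deduplicate(cl)
        qc = cell_qc(cl, mito_chroms=mito)
        state["classified"], state["qc"] = cl, qc
        pio.write_table(qc, out / "cell_qc.tsv")
        log_stage("classify", t0, pairs=len(cl),
                  valid=int((cl["category"] == "valid").sum()))

    if stages["callcells"]:
        t0 = time.time()
        cl, qc = state["classified"], state["qc"]
        curve = rank_barcodes(qc.set_index("cell_id")["unique_valid_pairs"])
        knees = find_knees(curve, sensitivity=cfg["callcells"]["sensitivity"],
                           contrast=cfg["callcells"]["contrast"])
        pio.write_table(knees.labels, out / "barcode_ranks.tsv")
        valid_cells = set(knees.labels.loc[knees.labels["label"] == "valid", "barcode"])
        uv = cl[(cl["category"] == "valid") & ~cl["duplicate"]
                & cl["cell_id"].isin(valid_cells)]
        result = {"knee1": knees.knee1, "knee2": knees.knee2,
                  "n_valid_cells": len(valid_cells)}
        if len(genomes) == 2 and valid_cells:
            sp = uv.assign(species=uv["chrom1"].map(chrom_species))
            counts = sp.pivot_table(index="cell_id", columns="species",
                                    values="read_id", aggfunc="count", fill_value=0)
            for tag in genomes:
                if tag not in counts.columns:
                    counts[tag] = 0
            call = assign_species(counts[list(genomes)],
                                  threshold=cfg["callcells"]["species_threshold"])
            pio.write_table(call.calls, out / "species_calls.tsv")
            est = collision_rate(call)
            result.update(n_doublets=est.n_doublets, collision_rate=est.rate)
            state["species"] = call
        state["valid_cells"] = valid_cells
        state["unique_valid"] = uv
        log_stage("callcells", t0, **result)

    if stages["tracks"]:
        t0 = time.time()
        tr = cfg["tracks"]
        uv = state["unique_valid"]
        cis = uv[uv["chrom1"] == uv["chrom2"]]
        bm = bin_contacts(cis, tr["bin_size"], chrom_lengths)
        if tr["balance"]:
            ice_balance(bm)
        params = InsulationParams(tr["bin_size"], tr["min_depth"],
                                  tr["max_depth"], tr["step"])
        big = [c for c, L in chrom_lengths.items()
               if L >= 2 * tr["max_depth"] + tr["bin_size"]]
        ins = insulation_scores(bm, params, balanced=tr["balance"], chroms=big)
        bd = call_boundaries(ins, BoundaryCallParams(delta=tr["delta"]))
        ev = compartment_eigenvector(bm, balanced=tr["balance"])
        pio.write_bedgraph(ins, out / "insulation.bedgraph")
        pio.write_bed(bd, out / "boundaries.bed")
        pio.write_bedgraph(ev, out / "compartments.bedgraph")
        state["bm"], state["insulation"], state["eigen"] = bm, ins, ev
        log_stage("tracks", t0, bins=bm.n_bins, boundaries=len(bd))

    if stages["melting"]:
        t0 = time.time()
        ml = cfg["melting"]
        sim = state["sim"]
        roi_spec = ml["roi"] or list(sim.structure.roi)
        roi = RegionOfInterest("roi", str(roi_spec[0]), int(roi_spec[1]), int(roi_spec[2]))
        uv = state["unique_valid"]
        guard = depth_guard(uv.groupby("cell_id").size(), threshold=ml["depth_guard"])
        pio.write_table(guard, out / "depth_guard.tsv")
        eq = downsample_per_cell(uv, ml["equal_depth"],
                                 rng_seed=stage_seed(cfg["seed"], "melting"))
        M = per_cell_insulation_matrix(eq, chrom_lengths, roi)
        clu = cluster_states(M)
        score = melting_score(M, clu)
        pio.write_table(clu.labels.rename("state").rename_axis("cell_id").reset_index(),
                        out / "cell_states.tsv")
        pio.write_table(pd.DataFrame([{
            "region": roi.label, "chrom": roi.chrom, "start": roi.start,
            "end": roi.end, "D": score.d, "p_value": score.p_value,
            "significant": score.significant, "n_melting_cells": len(clu.melting_cells),
            "n_concretion_cells": len(clu.concretion_cells), "stable": clu.stable,
        }]), out / "melting_scores.tsv")
        state["melting"] = (clu, score)
        log_stage("melting", t0, cells=M.shape[0], ks_d=round(score.d, 4))

    if stages["phasing"]:
        t0 = time.time()
        sim = state["sim"]
        uv = state["unique_valid"]
        tag, genome = next(iter(sim.genomes.items()))
        track = RepliTrack.from_intervals(
            sim.structure.repli_intervals(genome, "early"),
            sim.structure.repli_intervals(genome, "late"))
        own = uv[uv["chrom1"].map(chrom_species) == tag]
        rs = repli_score(own, track)
        result = {"cells_scored": len(rs)}
        try:
            hs = haploid_score(own, genome, threshold=cfg["phasing"]["haploid_threshold"])
            rs = rs.merge(hs, on="cell_id", how="left")
            if (hs["ploidy_call"] == "haploid").any() and \
               (hs["ploidy_call"] == "diploid").any():
                qc = state["qc"]
                result["trans_cis_comparison"] = group_compare_trans_cis(qc, hs)
        except ValueError:
            pass  # genome without sex chromosomes: repli-score only
        pio.write_table(rs, out / "phasing.tsv")
        log_stage("phasing", t0, **{k: v for k, v in result.items()
                                    if not isinstance(v, dict)})
    return state
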