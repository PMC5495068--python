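"""End-to-end orchestration: simulate -> tracks -> domains -> compartments
-> enrichment -> metaprofiles, driven by one structured config.

Every analysis threshold (W, G, FDR, the strict >80% gene rule, the 1-Mb
pericentromere distance filter) appears in the config with its standard
value as default, so a default run is the reproducible reference
profile. A manifest records the config hash, seed, per-stage outputs and
status; reruns with the same config and seed produce byte-identical
BED/TSV outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from . import compartments as comp
from . import io as pio
from . import profiles as prof
from . import stats as pstats
from .core import GenomeLayout, Interval
from .domains import (DomainSet, IslandParams, assign_enriched_genes,
                      call_islands, clip_to_arms, domain_summary,
                      intersect_replicates, islands_to_domains)
from .intervals import by_chrom, jaccard
from .simulate import (SimulationConfig, SyntheticDataset, generate_dataset,
                       write_dataset)
from .tracks import (BinnedTrack, bedgraph_to_track, bin_fragments, log2_ratio,
                     normalize_per_million)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "tracks", "domains", "compartments",
              "enrichment", "metaprofiles")

DEFAULT_CONFIG: dict = {
    "stages": list(ALL_STAGES),
    "simulation": {},             # SimulationConfig overrides
    "calling": {"window": 1000, "gap": 3000, "fdr": 0.01, "p_eligible": 0.2},
    "analysis": {
        "overview_window": 50_000,
        "binsize": 20_000,
        "pseudocount": 0.5,
        "enrichment_threshold": 0.8,
        "min_peri_distance": 1_000_000,
        "n_perm": 199,
        "shift_magnitudes": [50_000, 100_000],
        "flank": 20_000,
        "profile_window": 100,
        "body_bins": 40,
    },
    "inputs": {},                 # paths for non-simulated runs
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
        }, indent=2, sort_keys=True)


def load_config(config: dict | str | os.PathLike | None) -> dict:
    if config is None:
        user: dict = {}
    elif isinstance(config, dict):
        user = copy.deepcopy(config)
    else:
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in user.items():
        if key not in merged:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(merged[key], dict):
            merged[key].update(val or {})
        else:
            merged[key] = val
    bad = set(merged["stages"]) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    return merged


def _island_params(cfg: dict) -> IslandParams:
    c = cfg["calling"]
    return IslandParams(window=c["window"], gap=c["gap"], fdr=c["fdr"],
                        p_eligible=c["p_eligible"])


def _validate_inputs(cfg: dict) -> None:
    """For non-simulated runs, fail before any stage if inputs are missing."""
    stages = cfg["stages"]
    if "simulate" in stages:
        return
    inputs = cfg["inputs"]
    required = {"layout": ["layout"]}
    if "tracks" in stages or "domains" in stages:
        required["fragments"] = ["gfp_rep1", "igg_rep1"]
    if "compartments" in stages:
        required["hic"] = ["hic"]
    if "enrichment" in stages:
        required["annotation"] = ["genes"]
    missing = [key for group in required.values() for key in group
               if key not in inputs or not os.path.exists(str(inputs[key]))]
    if missing:
        raise FileNotFoundError(
            f"non-simulated run is missing inputs: {', '.join(sorted(missing))}")


def call_domains_from_fragments(
    dataset_fragments: dict, layout: GenomeLayout, params: IslandParams,
    n_replicates: int = 2, tissue: str = "synthetic",
) -> tuple[list[DomainSet], DomainSet]:
    """Per-replicate island calls plus their bp-level intersection."""
    replicate_sets: list[DomainSet] = []
    for rep in range(1, n_replicates + 1):
        chip = bin_fragments(dataset_fragments[f"GFP_rep{rep}"], layout, params.window)
        ctrl = bin_fragments(dataset_fragments[f"IgG_rep{rep}"], layout, params.window)
        islands = call_islands(chip, ctrl, layout, params)
        replicate_sets.append(islands_to_domains(islands, tissue=f"{tissue}_rep{rep}"))
    merged = replicate_sets[0]
    for other in replicate_sets[1:]:
        merged = intersect_replicates(merged, other)
    merged.tissue = tissue
    return replicate_sets, merged


def run_domain_recovery(
    sim_config: SimulationConfig, params: IslandParams = IslandParams(),
) -> dict:
    """The headline parameter-recovery analysis on one synthetic dataset.

    Simulates fragments, calls islands per replicate, intersects
    replicates, clips the calls to chromosome arms (the pericentromere is
    enriched by construction and not part of the arm-domain truth), and
    reports coverage, median length and bp-Jaccard against the truth.
    """
    ds = generate_dataset(sim_config, genotypes=("WT",))
    _, intersected = call_domains_from_fragments(
        ds.fragments, ds.layout, params, n_replicates=sim_config.n_replicates)
    called_arms = clip_to_arms(intersected, ds.layout)
    summary = domain_summary(called_arms, ds.layout)
    jac = jaccard(by_chrom(ds.truth.domains.intervals),
                  by_chrom(called_arms.intervals))
    return {
        "dataset": ds,
        "called": intersected,
        "called_arms": called_arms,
        "summary": summary,
        "jaccard": jac,
        "genome_coverage_pct": 100.0 * summary["genome_coverage"],
        "median_length_kb": (summary["median_length"] or 0.0) / 1000.0,
    }


def run_pipeline(config: dict | str | os.PathLike | None, seed: int,
                 outdir: str | os.PathLike) -> RunManifest:
    """Execute the configured stages in dependency order.

    Any stage failure aborts with the failing stage named. The manifest
    is written to ``<outdir>/manifest.json``.
    """
    cfg = load_config(config)
    _validate_inputs(cfg)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    cfg_bytes = yaml.safe_dump(cfg, sort_keys=True).encode()
    manifest = RunManifest(config_hash=hashlib.sha256(cfg_bytes).hexdigest()[:16],
                           seed=int(seed), version=__version__)
    state: dict = {}
    stage_order = [s for s in ALL_STAGES if s in cfg["stages"]]
    for stage in stage_order:
        try:
            outputs = _STAGE_FUNCS[stage](cfg, int(seed), outdir, state)
        except Exception as exc:
            manifest.stages[stage] = {"status": f"failed: {exc}", "outputs": []}
            _write_manifest(manifest, outdir)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages[stage] = {"status": "ok", "outputs": sorted(outputs)}
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: RunManifest, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())


# ------------------------------------------------------------------ stages


def _stage_simulate(cfg, seed, outdir, state) -> list[str]:
    sim_cfg = SimulationConfig.from_dict({**cfg["simulation"], "seed": seed})
    ds = generate_dataset(sim_cfg)
    simdir = os.path.join(outdir, "simulated")
    paths = write_dataset(ds, simdir)
    state["dataset"] = ds
    state["layout"] = ds.layout
    log.info("simulate: %d chromosomes, %d true domains, %d genes",
             len(ds.layout.chromosomes), len(ds.truth.domains.intervals),
             len(ds.genes))
    return list(paths.values())


def _load_external(cfg, state) -> None:
    inputs = cfg["inputs"]
    state["layout"] = pio.read_layout(inputs["layout"])
    frags = {}
    rep = 1
    while f"gfp_rep{rep}" in inputs:
        frags[f"GFP_rep{rep}"] = pio.read_fragments(inputs[f"gfp_rep{rep}"],
                                                    label=f"GFP_rep{rep}")
        frags[f"IgG_rep{rep}"] = pio.read_fragments(inputs[f"igg_rep{rep}"],
                                                    label=f"IgG_rep{rep}")
        rep += 1
    state["fragments"] = frags


def _get_fragments(cfg, state) -> dict:
    if "dataset" in state:
        return state["dataset"].fragments
    if "fragments" not in state:
        _load_external(cfg, state)
    return state["fragments"]


def _stage_tracks(cfg, seed, outdir, state) -> list[str]:
    layout = state["layout"]
    an = cfg["analysis"]
    frags = _get_fragments(cfg, state)
    outputs = []
    state["tracks"] = {}
    n_rep = sum(1 for k in frags if k.startswith("GFP_"))
    for window, tag in ((an["overview_window"], "overview"), (an["binsize"], "signal")):
        for rep in range(1, n_rep + 1):
            gfp = normalize_per_million(bin_fragments(frags[f"GFP_rep{rep}"], layout, window))
            igg = normalize_per_million(bin_fragments(frags[f"IgG_rep{rep}"], layout, window))
            ratio = log2_ratio(gfp, igg, pseudocount=an["pseudocount"])
            path = os.path.join(outdir, f"log2_{tag}_rep{rep}.bedGraph")
            pio.write_bedgraph(ratio.to_bedgraph(), path)
            outputs.append(path)
            state["tracks"][(tag, rep)] = ratio
    log.info("tracks: wrote %d log2-ratio tracks (pseudocount %.2g)",
             len(outputs), an["pseudocount"])
    return outputs


def _stage_domains(cfg, seed, outdir, state) -> list[str]:
    layout = state["layout"]
    params = _island_params(cfg)
    frags = _get_fragments(cfg, state)
    n_rep = sum(1 for k in frags if k.startswith("GFP_"))
    replicate_sets, intersected = call_domains_from_fragments(
        frags, layout, params, n_replicates=n_rep)
    outputs = []
    for i, dom in enumerate(replicate_sets, start=1):
        path = os.path.join(outdir, f"islands_rep{i}.bed")
        pio.write_bed(dom.intervals, path)
        outputs.append(path)
    path = os.path.join(outdir, "domains.bed")
    pio.write_bed(intersected.intervals, path)
    outputs.append(path)
    arms = clip_to_arms(intersected, layout)
    path = os.path.join(outdir, "domains_arms.bed")
    pio.write_bed(arms.intervals, path)
    outputs.append(path)
    summary = domain_summary(arms, layout)
    if "dataset" in state:
        summary["jaccard_truth"] = jaccard(
            by_chrom(state["dataset"].truth.domains.intervals),
            by_chrom(arms.intervals))
    path = os.path.join(outdir, "domain_summary.json")
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
    outputs.append(path)
    state["domains"] = intersected
    state["domains_arms"] = arms
    log.info("domains: W=%d G=%d FDR<%g -> %d intersected domains, "
             "%.1f%% of genome on arms",
             params.window, params.gap, params.fdr,
             len(intersected.intervals), 100 * summary["genome_coverage"])
    return outputs


def _stage_compartments(cfg, seed, outdir, state) -> list[str]:
    layout = state["layout"]
    an = cfg["analysis"]
    binsize = an["binsize"]
    if "dataset" in state:
        hic = state["dataset"].hic
    else:
        hic = {c: pio.read_dense_matrix(cfg["inputs"]["hic"].format(chrom=c))
               for c in layout.names}
    signal = state.get("tracks", {}).get(("signal", 1))
    if signal is None:
        raise RuntimeError("compartments requires the tracks stage (20-kb signal)")
    outputs = []
    rows = []
    state["compartments"] = []
    for chrom in layout.names:
        if chrom not in hic:
            continue
        for res in comp.compartments_for_chromosome(hic[chrom], layout, chrom,
                                                    binsize, signal):
            state["compartments"].append((chrom, res))
            for local_i, bin_i in enumerate(res.bin_indices):
                rows.append((chrom, int(bin_i) * binsize, (int(bin_i) + 1) * binsize,
                             res.pc1[local_i], res.labels[local_i], res.arm_id))
    path = os.path.join(outdir, "compartments.tsv")
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tpc1\tlabel\tarm\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    outputs.append(path)
    log.info("compartments: %d arms analysed", len(state["compartments"]))
    return outputs


def _stage_enrichment(cfg, seed, outdir, state) -> list[str]:
    layout = state["layout"]
    an = cfg["analysis"]
    domains = state.get("domains")
    if domains is None:
        raise RuntimeError("enrichment requires the domains stage")
    if "dataset" in state:
        genes = state["dataset"].genes
        loops = state["dataset"].loops
    else:
        expr = (pio.read_expression_tsv(cfg["inputs"]["expression"])
                if "expression" in cfg["inputs"] else None)
        genes = pio.read_gff3_genes(cfg["inputs"]["genes"], expression=expr)
        loops = (pio.read_bedpe(cfg["inputs"]["loops"])
                 if "loops" in cfg["inputs"] else [])
    report: dict = {}
    mags = tuple(an["shift_magnitudes"])
    for biotype in ("TE_gene", "protein_coding"):
        null = pstats.permutation_test(
            lambda d, b=biotype: pstats.count_genes_in_domains(genes, d, b),
            domains, layout, n_perm=an["n_perm"], magnitudes=mags,
            seed=seed, name=f"{biotype}_count")
        report[biotype] = {"observed": null.observed,
                           "null_mean": float(np.mean(null.null)),
                           "p_greater": null.p_greater}
    flags = assign_enriched_genes(genes, domains,
                                  threshold=an["enrichment_threshold"])
    pc = [g for g in genes if g.biotype == "protein_coding"]
    enr = [g.expression for g in pc if flags[g.gene_id]]
    non = [g.expression for g in pc if not flags[g.gene_id]]
    if enr and non:
        report["expression"] = pstats.rank_sum_compare(enr, non)
    if loops:
        counts = pstats.classify_loops(loops, domains)
        report["loops"] = {"intra": counts.intra, "across": counts.across,
                           "outside": counts.outside,
                           "excluded_trans": counts.excluded_trans}
    path = os.path.join(outdir, "enrichment.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    state["enriched_flags"] = flags
    state["genes"] = genes
    log.info("enrichment: strict >%.0f%% overlap rule, %d permutations, "
             "shifts %s", 100 * an["enrichment_threshold"], an["n_perm"], mags)
    return [path]


def _stage_metaprofiles(cfg, seed, outdir, state) -> list[str]:
    an = cfg["analysis"]
    layout = state["layout"]
    domains = state.get("domains_arms") or state.get("domains")
    if domains is None:
        raise RuntimeError("metaprofiles requires the domains stage")
    outputs = []
    # boundary profile of the domains themselves (step-shaped sanity track)
    bprof = prof.boundary_profile(domains.intervals, domains, layout,
                                  flank=an["flank"], window=an["profile_window"],
                                  group="domains")
    path = os.path.join(outdir, "boundary_domains.tsv")
    _write_profile(bprof, path)
    outputs.append(path)
    if "dataset" in state:
        ds = state["dataset"]
        peripheral, interior = prof.group_tes_by_location(ds.tes, domains)
        for genotype, tracks in ds.methylation.items():
            tag = genotype.replace("-like", "")
            for context, df in tracks.items():
                track = bedgraph_to_track(df, layout, an["profile_window"],
                                          normalization="ratio")
                for group_name, tes in (("peripheral", peripheral),
                                        ("interior", interior)):
                    ivs = [t.interval for t in tes]
                    if not ivs:
                        continue
                    p = prof.scaled_body_profile(track, ivs,
                                                 n_body_bins=an["body_bins"],
                                                 group=f"{tag}/{context}/{group_name}")
                    path = os.path.join(outdir, f"body_{tag}_{context}_{group_name}.tsv")
                    _write_profile(p, path)
                    outputs.append(path)
    log.info("metaprofiles: %d profiles written", len(outputs))
    return outputs


def _write_profile(p, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("position\tmean\tn\tgroup\n")
        for pos, mean, n in zip(p.positions, p.mean, p.n):
            fh.write(f"{pos}\t{mean:.6g}\t{n}\t{p.group}\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "tracks": _stage_tracks,
    "domains": _stage_domains,
    "compartments": _stage_compartments,
    "enrichment": _stage_enrichment,
    "metaprofiles": _stage_metaprofiles,
}
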