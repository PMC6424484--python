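"""End-to-end pipeline: simulate/load, scan, curate, call, network, infer.

Each stage is a plain function over the library so it can be driven from
the CLI, the analysis scripts, or tests; ``run_pipeline`` chains them
and writes every report as TSV/JSON under an output directory.  Outputs
are deterministic for a fixed seed and input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import deletions as dels
from . import grouping, haplonet, phylogeo, popgen, traits
from .config import PipelineConfig
from .datatypes import DepthTable, GenotypeMatrix, SampleTable
from .io import write_depth_table, write_sample_table, write_vcf
from .simulate import (
    SimConfig,
    default_genes,
    simulate_dataset,
    simulate_depths,
    simulate_phenotypes,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ----------------------------------------------------------------------
# stage: simulate


def stage_simulate(sim_cfg: SimConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, samples, truth = simulate_dataset(sim_cfg)
    depths = simulate_depths(truth, samples, default_genes(), rng_seed=sim_cfg.rng_seed + 1)
    phenotypes = simulate_phenotypes(sim_cfg, truth, samples, rng_seed=sim_cfg.rng_seed + 2)
    write_vcf(matrix, outdir / "genotypes.vcf")
    write_sample_table(samples, outdir / "samples.tsv")
    write_depth_table(depths, outdir / "depths.tsv")
    _write(phenotypes, outdir / "phenotypes.tsv")
    truth.to_json(outdir / "truth.json")
    return {
        "matrix": matrix, "samples": samples, "truth": truth,
        "depths": depths, "phenotypes": phenotypes, "sim_cfg": sim_cfg,
    }


# ----------------------------------------------------------------------
# stage: window statistics, Fst, LD, f4, sweep scan


def group_matrices(matrix: GenotypeMatrix, samples: SampleTable) -> dict[str, GenotypeMatrix]:
    return {
        g: matrix.take_samples(samples.ids_in_group(g))
        for g in sorted(samples.df["group"].unique())
    }


def stage_stats(cfg: PipelineConfig, matrix: GenotypeMatrix, samples: SampleTable, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    by_group = group_matrices(matrix, samples)

    stats_rows = []
    window_stats = {}
    for g, gm in by_group.items():
        ws = popgen.window_diversity(gm, cfg.window_size, cfg.min_window_data_fraction)
        window_stats[g] = ws
        for w in ws:
            stats_rows.append((g,) + dataclasses.astuple(w))
    _write(
        pd.DataFrame(
            stats_rows,
            columns=["group", "chrom", "start", "end", "n_sites_typed",
                     "data_fraction", "pi", "theta_w", "tajima_d"],
        ),
        outdir / "window_stats.tsv",
    )

    fst_rows = []
    names = sorted(by_group)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for w in popgen.hudson_fst(by_group[a], by_group[b], cfg.window_size):
                fst_rows.append((a, b, w.chrom, w.start, w.end, w.fst, w.n_sites))
    _write(
        pd.DataFrame(fst_rows, columns=["group_a", "group_b", "chrom", "start", "end", "fst", "n_sites"]),
        outdir / "fst_windows.tsv",
    )

    ld_rows = []
    for g, gm in by_group.items():
        for b in popgen.ld_decay(gm, cfg.ld_window, cfg.ld_bin):
            ld_rows.append((g, b.distance_bin_start, b.distance_bin_end, b.mean_r2, b.n_pairs))
    _write(
        pd.DataFrame(ld_rows, columns=["group", "bin_start", "bin_end", "mean_r2", "n_pairs"]),
        outdir / "ld_decay.tsv",
    )
    return {"by_group": by_group, "window_stats": window_stats}


def stage_sweep(
    cfg: PipelineConfig,
    matrix: GenotypeMatrix,
    samples: SampleTable,
    carrier_ids_by_locus: dict[str, list[str]],
    outdir: Path,
) -> dict:
    """pi_wild / pi_domesticate scan per locus, domesticates restricted to
    derived carriers (mirrors scanning swept backgrounds only)."""
    outdir.mkdir(parents=True, exist_ok=True)
    wild_ids = [
        s for s in samples.ids_of_species("wild")
        if samples.group_of()[s] != "FERAL"
    ]
    wild_stats = popgen.window_diversity(
        matrix.take_samples(wild_ids), cfg.window_size, cfg.min_window_data_fraction
    )
    sweeps = {}
    rows = []
    for locus_id, carrier_ids in carrier_ids_by_locus.items():
        if len(carrier_ids) < 2:
            log.warning("locus %s: fewer than 2 carriers; sweep scan skipped", locus_id)
            continue
        dom_stats = popgen.window_diversity(
            matrix.take_samples(carrier_ids), cfg.window_size, cfg.min_window_data_fraction
        )
        scan = popgen.sweep_scan(wild_stats, dom_stats)
        sweeps[locus_id] = scan
        for w in scan:
            rows.append((locus_id, w.chrom, w.start, w.end, w.pi_wild, w.pi_dom,
                         w.ratio, w.top1pct_flag))
    _write(
        pd.DataFrame(rows, columns=["locus", "chrom", "start", "end", "pi_wild",
                                    "pi_dom", "ratio", "top1pct_flag"]),
        outdir / "sweep_scan.tsv",
    )
    return {"sweeps": sweeps}


# ----------------------------------------------------------------------
# stage: grouping / core set


def stage_group(cfg: PipelineConfig, matrix: GenotypeMatrix, samples: SampleTable, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    dom_ids = samples.ids_of_species("domesticate")
    filtered = popgen.filter_sites(matrix, cfg.min_call_rate, cfg.min_maf)
    thinned = popgen.thin_sites(filtered, seed=cfg.rng_seed)
    dom_matrix = thinned.take_samples(dom_ids)
    dm = grouping.pairwise_distance(dom_matrix)
    pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
        outdir / "distances.tsv", sep="\t", float_format=FLOAT_FMT
    )
    labels = {s: samples.group_of()[s] for s in dm.sample_ids}
    core = grouping.iterative_core_filter(dm, labels, cfg.silhouette_threshold)
    report = core.final_report
    removed_at = {}
    for it, removed in enumerate(core.removed_per_iteration, start=1):
        for s in removed:
            removed_at[s] = it
    sil_rows = [
        (s, labels[s], a, b, sc, removed_at.get(s, 0))
        for s, a, b, sc in zip(report.sample_ids, report.a, report.b, report.s)
    ]
    for s, it in removed_at.items():
        sil_rows.append((s, labels[s], np.nan, np.nan, np.nan, it))
    _write(
        pd.DataFrame(sil_rows, columns=["sample_id", "group", "a", "b", "s", "iteration_removed"]),
        outdir / "silhouette.tsv",
    )
    with open(outdir / "core_set.json", "w") as fh:
        json.dump(
            {
                "retained": core.retained,
                "iterations_run": core.iterations_run,
                "stopped_on_small_group": core.stopped_on_small_group,
            },
            fh, indent=1,
        )
    tree = grouping.neighbor_joining(dm)
    (outdir / "nj_tree.nwk").write_text(tree + "\n")
    coords = grouping.classical_mds(dm, k=2)
    _write(
        pd.DataFrame(
            {"sample_id": dm.sample_ids, "mds1": coords[:, 0], "mds2": coords[:, 1]}
        ),
        outdir / "mds.tsv",
    )
    return {"core": core, "distance": dm, "mds": coords}


# ----------------------------------------------------------------------
# stage: deletions


def stage_deletions(
    cfg: PipelineConfig,
    matrix: GenotypeMatrix,
    samples: SampleTable,
    depths: DepthTable,
    gene_pairs: list[tuple[str, str]],
    outdir: Path,
    desert_min_gap_bp: int = 8_000,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    all_calls = {}
    call_rows = []
    freq_frames = []
    for target, control in gene_pairs:
        calls = dels.call_deletions(
            depths, target, control, cfg.deletion_ratio_threshold, cfg.control_min_depth
        )
        all_calls[target] = calls
        call_rows += [
            (c.sample_id, c.gene_id, c.target_median, c.control_median, c.ratio, c.call)
            for c in calls
        ]
        freq = dels.deletion_frequency(calls, samples)
        freq.insert(0, "gene", target)
        freq_frames.append(freq)
    _write(
        pd.DataFrame(call_rows, columns=["sample_id", "gene", "target_median",
                                         "control_median", "ratio", "call"]),
        outdir / "deletion_calls.tsv",
    )
    _write(pd.concat(freq_frames, ignore_index=True), outdir / "deletion_frequency.tsv")

    alt, called = matrix.allele_counts()
    call_rate = called / (2 * matrix.n_samples)
    passing = call_rate >= cfg.min_call_rate
    deserts = dels.snp_desert_regions(matrix, passing, desert_min_gap_bp)
    _write(
        pd.DataFrame(
            [(d.chrom, d.left_passing_pos, d.right_passing_pos, d.length) for d in deserts],
            columns=["chrom", "left_passing_pos", "right_passing_pos", "length"],
        ),
        outdir / "snp_deserts.tsv",
    )
    return {"calls": all_calls, "deserts": deserts}


# ----------------------------------------------------------------------
# stage: haplotype networks and origins


def stage_hapnet_origin(
    cfg: PipelineConfig,
    matrix: GenotypeMatrix,
    samples: SampleTable,
    loci: list,
    derived_samples_by_locus: dict[str, set[str]],
    outdir: Path,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    species_of = samples.species_of()
    networks = {}
    origins = {}
    origin_rows = []
    for locus in loci:
        h = haplonet.extract_haplotypes(matrix, locus.chrom, locus.focal_start, locus.focal_end)
        if locus.kind == "snp":
            h = haplonet.set_causal_from_allele(h, matrix, locus.chrom, locus.pos)
        else:
            status = derived_samples_by_locus[locus.locus_id]
            h = haplonet.set_causal_from_sample_status(
                h, status["derived"], status["unknown"]
            )
        wild_rows = [i for i, (sid, _) in enumerate(h.carriers) if species_of[sid] == "wild"]
        dom_rows = [i for i, (sid, _) in enumerate(h.carriers) if species_of[sid] == "domesticate"]
        cleaned, scan = haplonet.nonrecombining_scan(h, wild_rows, dom_rows, cfg.fg_error_freq)
        _write(
            pd.DataFrame(scan.failing_pairs, columns=["pos_i", "pos_j", "partition"]),
            outdir / f"{locus.locus_id}_fourgamete.tsv",
        )
        if scan.status == "rejected":
            log.warning("locus %s: recombination in domesticates; region rejected", locus.locus_id)
            continue
        nodes = haplonet.collapse_haplotypes(cleaned)
        net = haplonet.hamming_mst(nodes)
        networks[locus.locus_id] = net
        net.to_graphml(outdir / f"{locus.locus_id}_network.graphml")
        _write(net.node_table(), outdir / f"{locus.locus_id}_nodes.tsv")
        try:
            origin = phylogeo.locus_origin(net, samples, locus_id=locus.locus_id)
        except Exception as exc:  # no ancestral/derived nodes observed
            log.warning("locus %s: origin not inferred (%s)", locus.locus_id, exc)
            continue
        origins[locus.locus_id] = origin
        for region, score in sorted(origin.scores.items()):
            origin_rows.append(
                (locus.locus_id, region, score, region in origin.top_regions,
                 origin.founding_label, ";".join(origin.ancestral_labels),
                 origin.n_derived, origin.n_ancestral, origin.status)
            )
    _write(
        pd.DataFrame(
            origin_rows,
            columns=["locus", "region", "overlap_score", "top_region", "founding_haplotype",
                     "ancestral_haplotypes", "n_derived", "n_ancestral", "status"],
        ),
        outdir / "origin_report.tsv",
    )
    with open(outdir / "origin_report.json", "w") as fh:
        json.dump(
            {
                lid: {
                    "top_regions": o.top_regions,
                    "scores": o.scores,
                    "founding": o.founding_label,
                    "status": o.status,
                    "n_derived": o.n_derived,
                    "n_ancestral": o.n_ancestral,
                }
                for lid, o in origins.items()
            },
            fh, indent=1,
        )
    return {"networks": networks, "origins": origins}


# ----------------------------------------------------------------------
# stage: traits


def stage_traits(
    phenotypes: pd.DataFrame,
    samples: SampleTable,
    sh1_status: dict[str, str],
    sh4_status: dict[str, str],
    outdir: Path,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    records = traits.score_records(phenotypes)
    scores = {r.sample_id: r.ses_score for r in records}
    _write(
        pd.DataFrame(
            [(r.sample_id, r.percent_shattering, r.ses_score) for r in records],
            columns=["sample_id", "percent_shattering", "ses_score"],
        ),
        outdir / "ses_scores.tsv",
    )
    group_of = samples.group_of()
    dom_groups = sorted(
        g for g in samples.df["group"].unique() if g.startswith("DOM") or g.startswith("OG")
    )
    by_group = {
        g: [scores[s] for s in samples.ids_in_group(g) if s in scores]
        for g in dom_groups
    }
    pmat = traits.pairwise_mwu(by_group)
    pmat.to_csv(outdir / "mwu_pvalues.tsv", sep="\t", float_format=FLOAT_FMT)
    conc = traits.concordance_table(sh1_status, sh4_status, scores, group_of)
    _write(conc, outdir / "concordance.tsv")
    return {"scores": scores, "mwu": pmat, "concordance": conc}


# ----------------------------------------------------------------------
# full run


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    sim_cfg: SimConfig | None = None,
) -> dict:
    """Run every stage on a synthetic dataset and write all reports.

    Any stage failure aborts with the stage name and cause.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    if sim_cfg is None:
        sim_cfg = SimConfig(rng_seed=cfg.rng_seed)
    with open(outdir / "run_params.json", "w") as fh:
        json.dump(
            {
                "pipeline_config": dataclasses.asdict(cfg),
                "sim_config": {
                    k: v for k, v in dataclasses.asdict(sim_cfg).items() if k != "loci"
                },
                "loci": [l.locus_id for l in sim_cfg.loci],
            },
            fh, indent=1,
        )
    state: dict = {}
    stage = "simulate"
    try:
        state.update(stage_simulate(sim_cfg, outdir / "data"))
        stage = "stats"
        state.update(stage_stats(cfg, state["matrix"], state["samples"], outdir / "stats"))
        stage = "deldetect"
        deletion_loci = [l for l in sim_cfg.loci if l.kind == "gene_deletion"]
        gene_pairs = [(l.locus_id, f"ctrl_{l.chrom}") for l in deletion_loci]
        state.update(
            stage_deletions(cfg, state["matrix"], state["samples"], state["depths"],
                            gene_pairs, outdir / "deletions")
        )
        stage = "sweep"
        carriers = carrier_sets(state, sim_cfg)
        state.update(
            stage_sweep(cfg, state["matrix"], state["samples"],
                        {k: sorted(v) for k, v in carriers.items()}, outdir / "sweep")
        )
        stage = "group"
        state.update(stage_group(cfg, state["matrix"], state["samples"], outdir / "grouping"))
        stage = "hapnet/origin"
        hapnet_status = {
            l.locus_id: {
                "derived": {c.sample_id for c in state["calls"][l.locus_id] if c.call == "deleted"},
                "unknown": {c.sample_id for c in state["calls"][l.locus_id] if c.call == "no_call"},
            }
            for l in sim_cfg.loci
            if l.kind == "gene_deletion"
        }
        state.update(
            stage_hapnet_origin(cfg, state["matrix"], state["samples"], sim_cfg.loci,
                                hapnet_status, outdir / "hapnet")
        )
        stage = "traits"
        sh1, sh4 = shattering_status(state, sim_cfg)
        state.update(
            stage_traits(state["phenotypes"], state["samples"], sh1, sh4, outdir / "traits")
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return state


def recovery_replicate(
    seed: int,
    sim_cfg: SimConfig | None = None,
    cfg: PipelineConfig | None = None,
) -> dict:
    """One synthetic replicate scored against its own ground truth.

    Runs the data-dependent recovery path — simulate, depth-based
    deletion calls, carrier-restricted sweep scan, haplotype network and
    origin inference — and reports, per locus: whether the seeded origin
    region is the top-ranked region, whether the window containing the
    causal position is flagged by the top-1% scan, and the number of
    deletion-call errors against truth.
    """
    if sim_cfg is None:
        sim_cfg = SimConfig(rng_seed=seed)
    if cfg is None:
        cfg = PipelineConfig(rng_seed=seed)
    matrix, samples, truth = simulate_dataset(sim_cfg)
    depths = simulate_depths(truth, samples, default_genes(), rng_seed=sim_cfg.rng_seed + 1)
    state = {"matrix": matrix, "samples": samples, "truth": truth, "depths": depths}

    deletion_loci = [l for l in sim_cfg.loci if l.kind == "gene_deletion"]
    gene_pairs = [(l.locus_id, f"ctrl_{l.chrom}") for l in deletion_loci]
    calls = {
        target: dels.call_deletions(depths, target, control,
                                    cfg.deletion_ratio_threshold, cfg.control_min_depth)
        for target, control in gene_pairs
    }
    state["calls"] = calls
    deletion_errors = {}
    for l in deletion_loci:
        errors = 0
        for c in calls[l.locus_id]:
            want = truth.deletions[l.locus_id].get(c.sample_id, False)
            got = c.call
            if got == "no_call" or (got == "deleted") != want:
                errors += 1
        deletion_errors[l.locus_id] = errors

    carriers = carrier_sets(state, sim_cfg)
    wild_ids = [s for s in samples.ids_of_species("wild") if samples.group_of()[s] != "FERAL"]
    wild_stats = popgen.window_diversity(
        matrix.take_samples(wild_ids), cfg.window_size, cfg.min_window_data_fraction
    )
    sweep_hit = {}
    for l in sim_cfg.loci:
        ids = sorted(carriers[l.locus_id])
        if len(ids) < 2:
            sweep_hit[l.locus_id] = False
            continue
        dom_stats = popgen.window_diversity(
            matrix.take_samples(ids), cfg.window_size, cfg.min_window_data_fraction
        )
        scan = popgen.sweep_scan(wild_stats, dom_stats)
        hits = [
            w.top1pct_flag
            for w in scan
            if w.chrom == l.chrom and w.start <= l.pos < w.end
        ]
        sweep_hit[l.locus_id] = bool(hits and hits[0])

    species_of = samples.species_of()
    origin_ok = {}
    top_regions = {}
    for l in sim_cfg.loci:
        h = haplonet.extract_haplotypes(matrix, l.chrom, l.focal_start, l.focal_end)
        if l.kind == "snp":
            h = haplonet.set_causal_from_allele(h, matrix, l.chrom, l.pos)
        else:
            h = haplonet.set_causal_from_sample_status(
                h,
                {c.sample_id for c in calls[l.locus_id] if c.call == "deleted"},
                {c.sample_id for c in calls[l.locus_id] if c.call == "no_call"},
            )
        wild_rows = [i for i, (sid, _) in enumerate(h.carriers) if species_of[sid] == "wild"]
        dom_rows = [i for i, (sid, _) in enumerate(h.carriers) if species_of[sid] == "domesticate"]
        cleaned, scan_rep = haplonet.nonrecombining_scan(h, wild_rows, dom_rows, cfg.fg_error_freq)
        if scan_rep.status == "rejected":
            origin_ok[l.locus_id] = False
            top_regions[l.locus_id] = []
            continue
        net = haplonet.hamming_mst(haplonet.collapse_haplotypes(cleaned))
        try:
            origin = phylogeo.locus_origin(net, samples, locus_id=l.locus_id)
        except Exception:
            origin_ok[l.locus_id] = False
            top_regions[l.locus_id] = []
            continue
        want = sim_cfg.region_country(truth.origin_region[l.locus_id])
        top_regions[l.locus_id] = origin.top_regions
        origin_ok[l.locus_id] = origin.top_regions == [want]
    return {
        "origin_ok": origin_ok,
        "top_regions": top_regions,
        "sweep_hit": sweep_hit,
        "deletion_errors": deletion_errors,
        "truth": truth,
    }


def carrier_sets(state: dict, sim_cfg: SimConfig) -> dict[str, set[str]]:
    """Derived-carrier sample sets per locus, inferred from the data:
    deletion calls for deletion loci, the causal allele for SNP loci.
    Only domesticate-species samples count as sweep carriers."""
    matrix: GenotypeMatrix = state["matrix"]
    samples: SampleTable = state["samples"]
    dom = set(samples.ids_of_species("domesticate"))
    out: dict[str, set[str]] = {}
    for locus in sim_cfg.loci:
        if locus.kind == "gene_deletion":
            calls = state["calls"][locus.locus_id]
            out[locus.locus_id] = {
                c.sample_id for c in calls if c.call == "deleted" and c.sample_id in dom
            }
        else:
            site = np.flatnonzero((matrix.chrom == locus.chrom) & (matrix.pos == locus.pos))
            h = matrix.genotypes[:, :, site[0]]
            carrier = np.any(h == 1, axis=1)
            out[locus.locus_id] = {
                s for s, c in zip(matrix.sample_ids, carrier) if c and s in dom
            }
    return out


def shattering_status(state: dict, sim_cfg: SimConfig) -> tuple[dict[str, str], dict[str, str]]:
    """(sh1-like deletion status, sh4-like allele status) per sample."""
    matrix: GenotypeMatrix = state["matrix"]
    sh1: dict[str, str] = {}
    sh4: dict[str, str] = {}
    for locus in sim_cfg.loci:
        if locus.trait != "shattering":
            continue
        if locus.kind == "gene_deletion":
            for c in state["calls"][locus.locus_id]:
                sh1[c.sample_id] = {"deleted": "deleted", "present": "intact"}.get(
                    c.call, "no_call"
                )
        else:
            site = np.flatnonzero((matrix.chrom == locus.chrom) & (matrix.pos == locus.pos))
            h = matrix.genotypes[:, :, site[0]]
            for s, row in zip(matrix.sample_ids, h):
                sh4[s] = "causal" if np.any(row == 1) else "other"
    return sh1, sh4
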