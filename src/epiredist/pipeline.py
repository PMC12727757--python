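"""End-to-end orchestration: simulate -> normalize -> cluster -> metagene ->
genesets -> hic -> loops -> report, with a hashed output manifest.

The pipeline is deterministic: one master seed fans out to per-component
seeds, every float is written in exact round-trip form, JSON is key-sorted and
no timestamps enter any output, so two runs with the same config and seed
produce byte-identical manifests.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .compartments import (
    cis_range_fractions,
    compartment_score,
    compartment_shift_counts,
    oe_transform,
    saddle_strength,
    write_coo_matrix,
    write_dense_matrix,
)
from .genome import BinnedTrack, GenomicsError
from .genesets import build_matched_gene_sets, count_expression_shifts, gene_mark_change
from .loops import find_lost_loops, loop_anchor_enhancer_genes, write_bedpe
from .metagene import MetageneParams, compute_metagene_matrix, select_gene_groups, write_metagene_matrix
from .redistribution import (
    ClusterParams,
    cluster_redistribution,
    consolidate_clusters,
    signal_fraction_in_regions,
)
from .simulate import (
    make_genome_annotation,
    simulate_contact_maps,
    simulate_expression_response,
    simulate_mark_tracks,
)
from .tracknorm import (
    NormalizationParams,
    depth_normalize,
    input_log2_ratio,
    ms_calibrate,
    peakiness,
    quantitative_scale,
)

log = logging.getLogger("epiredist")

STAGES = ("simulate", "normalize", "cluster", "metagene", "genesets", "hic",
          "loops", "report")

_KNOWN_KEYS = {"seed", "simulate", "normalize", "cluster", "metagene",
               "genesets", "hic", "loops", "foci"}


def default_config() -> dict:
    """The default desk-scale fixture configuration."""
    return {
        "seed": 0,
        "simulate": {
            "genome": {"n_chrom": 2, "chrom_length_bp": 20_000_000,
                       "gene_density": 5.0, "domain_fraction": 0.25},
            "tracks": {"bin_size": 100_000, "depth_per_condition": 2e6,
                       "dispersion": 0.1},
            "contacts": {"bin_size": 100_000, "decay_exponent": 1.0,
                         "compartment_contrast_parental": 1.0,
                         "compartment_contrast_treated": 0.3,
                         "loop_strength": 2.0},
            "expression": {"effect_lfc": 2.0, "noise_sd": 0.5},
        },
        "normalize": {"pseudocount": 1e-15, "clip_cap": 100.0,
                      "peakiness_bin": 100_000, "peakiness_top_fraction": 0.01},
        "cluster": {"min_points": 25, "eps": 5.0, "merge_gap": 1_000_000},
        "metagene": {"n": 20, "upstream": 2000, "downstream": 2000,
                     "body": 20000, "bin": 500},
        "genesets": {"fpkm_lo": 1.0, "fpkm_hi": 40.0, "baseline_min": 1.0},
        "hic": {"q": 0.20, "ab_mode": "saddle-corner"},
        "loops": {"span_cutoff": 500_000, "tolerance_bins": 0},
    }


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise GenomicsError(f"unknown config keys: {sorted(unknown)}")
    if "simulate" not in config:
        raise GenomicsError("config requires a 'simulate' block (fixture mode)")
    return config


def _jwrite(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(
    config: dict, outdir, seed: int | None = None, only: list[str] | None = None
) -> dict:
    """Execute the stages in dependency order and return the manifest.

    ``only`` restricts which stages *emit outputs*; upstream in-memory results
    are still computed as needed.  Any stage failure aborts with the stage
    name; partial outputs keep a ``.partial`` marker file.
    """
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(config.get("seed", 0) if seed is None else seed)
    selected = set(only or STAGES)
    bad = selected - set(STAGES)
    if bad:
        raise GenomicsError(f"unknown stage(s): {sorted(bad)}")
    files: dict[str, Path] = {}
    results: dict = {"seed": master}
    marker = outdir / ".partial"
    marker.write_text("run in progress\n")
    effective = dict(config)
    effective["seed"] = master
    (outdir / "config.used.yaml").write_text(
        yaml.safe_dump(effective, sort_keys=True)
    )
    files["config"] = outdir / "config.used.yaml"

    stage = "simulate"
    try:
        sim = config["simulate"]
        layout, genes, enhancers, truth = make_genome_annotation(
            seed=master, **sim.get("genome", {})
        )
        parental_c, treated_c, input_c, cal = simulate_mark_tracks(
            truth, **sim.get("tracks", {})
        )
        matrices, loop_sets = simulate_contact_maps(truth, **sim.get("contacts", {}))
        deltas = simulate_expression_response(truth, **sim.get("expression", {}))
        log.info("simulate: %d genes, %d domains, %d loops",
                 len(genes), len(truth.domains), len(truth.loops))
        if stage in selected:
            files.update(write_fixture_bundle(
                outdir, layout, genes, enhancers, truth,
                parental_c, treated_c, input_c, cal, matrices, loop_sets, deltas,
            ))

        stage = "normalize"
        ncfg = dict(config.get("normalize", {}))
        params = NormalizationParams(
            pseudocount=ncfg.get("pseudocount", 1e-15),
            clip_cap=ncfg.get("clip_cap", 100.0),
            peakiness_top_fraction=ncfg.get("peakiness_top_fraction", 0.01),
            peakiness_bin=ncfg.get("peakiness_bin", 1000),
        )
        mark = "H3K9me3"
        scaled, ms_tracks, cpm = {}, {}, {}
        for cond, track in (("parental", parental_c), ("treated", treated_c)):
            total = float(track.values.sum())
            cpm[cond] = depth_normalize(track, total)
            pct = cal.pct(mark, cond)
            ms_tracks[cond] = ms_calibrate(cpm[cond], pct, params)
            ratio = input_log2_ratio(
                track, total, input_c, float(input_c.values.sum()), params
            )
            scaled[cond] = quantitative_scale(ratio, pct)
        pk = {c: peakiness(cpm[c], None, params) for c in ("parental", "treated")}
        results["normalize"] = {
            "ms_pct": {c: cal.pct(mark, c) for c in ("parental", "treated")},
            "peakiness": pk,
        }
        if stage in selected:
            for cond in ("parental", "treated"):
                p = outdir / f"{cond}.msnorm.bedgraph"
                eio.write_bedgraph(ms_tracks[cond], p)
                files[f"msnorm_{cond}"] = p
                p = outdir / f"{cond}.scaled.bedgraph"
                eio.write_bedgraph(scaled[cond], p)
                files[f"scaled_{cond}"] = p
            p = outdir / "normalize.stats.json"
            _jwrite(results["normalize"], p)
            files["normalize_stats"] = p

        stage = "cluster"
        ccfg = dict(config.get("cluster", {}))
        cparams = ClusterParams(
            min_points=ccfg.get("min_points", 1000),
            eps=ccfg.get("eps", 1000.0),
            merge_gap=ccfg.get("merge_gap", 1_000_000),
        )
        clusters = consolidate_clusters(
            cluster_redistribution(scaled["parental"], scaled["treated"], cparams),
            cparams,
        )
        fracs = {
            cond: {
                "A": signal_fraction_in_regions(cpm[cond], clusters.regions_a),
                "B": signal_fraction_in_regions(cpm[cond], clusters.regions_b),
            }
            for cond in ("parental", "treated")
        }
        jac = clusters.regions_b.jaccard(truth.domains)
        results["cluster"] = {"signal_fraction_pct": fracs,
                              "jaccard_b_vs_planted": jac,
                              "n_regions_a": len(clusters.regions_a),
                              "n_regions_b": len(clusters.regions_b)}
        log.info("cluster: Jaccard(B, planted)=%.3f", jac)
        if stage in selected:
            import pandas as pd

            rows_a = clusters.regions_a.df.assign(name="A")
            rows_b = clusters.regions_b.df.assign(name="B")
            regions = pd.concat([rows_a, rows_b], ignore_index=True)
            from .genome import IntervalSet

            p = outdir / "cluster.regions.bed"
            eio.write_bed(IntervalSet(regions).sorted(layout), p, columns=4)
            files["cluster_regions"] = p
            p = outdir / "cluster.labels.tsv"
            bins = layout.bins(ccfg.get("bin_size", scaled["parental"].bin_size)).df
            bins["label"] = clusters.labels
            bins.to_csv(p, sep="\t", index=False)
            files["cluster_labels"] = p
            p = outdir / "cluster.stats.json"
            _jwrite(results["cluster"], p)
            files["cluster_stats"] = p

        stage = "metagene"
        mcfg = dict(config.get("metagene", {}))
        mg_n = mcfg.get("n", 2000)
        mparams = MetageneParams(
            upstream=mcfg.get("upstream", 2000), downstream=mcfg.get("downstream", 2000),
            body=mcfg.get("body", 20000), bin=mcfg.get("bin", 500),
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            groups = select_gene_groups(genes, n=mg_n, seed=master)
        profiles = {}
        for gname in ("silent", "low", "high"):
            ids = getattr(groups, gname)
            if not ids:
                continue
            matrix, colmean = compute_metagene_matrix(
                ms_tracks["treated"], genes, ids, mparams
            )
            profiles[gname] = [float(v) for v in colmean]
            if stage in selected:
                p = outdir / f"metagene.{gname}.tsv"
                write_metagene_matrix(matrix, mparams, p)
                files[f"metagene_{gname}"] = p
        results["metagene"] = {"group_sizes": {g: len(getattr(groups, g))
                                               for g in ("silent", "low", "high")},
                               "column_means": profiles}
        if stage in selected:
            p = outdir / "metagene.profiles.json"
            _jwrite(results["metagene"], p)
            files["metagene_profiles"] = p

        stage = "genesets"
        gcfg = dict(config.get("genesets", {}))
        matched = build_matched_gene_sets(
            genes, truth.domains,
            fpkm_lo=gcfg.get("fpkm_lo", 9.0), fpkm_hi=gcfg.get("fpkm_hi", 12.0),
            baseline_min=gcfg.get("baseline_min", 1.0), seed=master,
        )
        sc_in, sc_ctrl = count_expression_shifts(
            matched.in_domain, matched.control, deltas
        )
        gmc = gene_mark_change(ms_tracks["parental"], ms_tracks["treated"], genes)
        dom_genes = genes.df["gene_id"][
            genes.intervals().overlaps_any(truth.domains)
        ]
        sub = gmc[gmc["gene_id"].isin(set(dom_genes))]
        frac_loss = float((sub["log2fc"] < 0).mean()) if len(sub) else float("nan")
        results["genesets"] = {
            "matched_set_size": len(matched.in_domain),
            "in_domain": {"up": sc_in.n_up, "down": sc_in.n_down, "zero": sc_in.n_zero},
            "control": {"up": sc_ctrl.n_up, "down": sc_ctrl.n_down,
                        "zero": sc_ctrl.n_zero},
            "ranksum_p": sc_in.pvalue,
            "in_domain_gene_loss_fraction": frac_loss,
        }
        if stage in selected:
            p = outdir / "genesets.matched.tsv"
            with open(p, "w") as fh:
                fh.write(f"# fpkm_window={matched.fpkm_window} seed={matched.seed}\n")
                fh.write("gene_id\tset\n")
                for gid in matched.in_domain:
                    fh.write(f"{gid}\tin_domain\n")
                for gid in matched.control:
                    fh.write(f"{gid}\tcontrol\n")
            files["genesets_matched"] = p
            p = outdir / "genesets.genemark.tsv"
            gmc.to_csv(p, sep="\t", index=False)
            files["genesets_genemark"] = p
            p = outdir / "genesets.stats.json"
            _jwrite(results["genesets"], p)
            files["genesets_stats"] = p

        stage = "hic"
        hcfg = dict(config.get("hic", {}))
        q = hcfg.get("q", 0.20)
        ab_mode = hcfg.get("ab_mode", "saddle-corner")
        hic_bin = sim.get("contacts", {}).get("bin_size", 100_000)
        probe = BinnedTrack(
            layout, hic_bin, np.zeros(layout.total_bins(hic_bin)), "count"
        )
        domain_frac = probe.region_weights(truth.domains)
        offsets = layout.bin_offsets(hic_bin)
        n_bins = layout.n_bins(hic_bin)
        hic_res: dict = {}
        score_vectors: dict[str, np.ndarray] = {}
        for cond in ("parental", "treated"):
            strengths_aa, strengths_bb, longs, shorts = [], [], [], []
            svec = np.full(layout.total_bins(hic_bin), np.nan)
            for chrom, m in matrices[cond].items():
                off, n = offsets[chrom], n_bins[chrom]
                phasing = -domain_frac[off: off + n]  # A-like bins score high
                oe = oe_transform(m)
                score = compartment_score(m, phasing)
                svec[off: off + n] = score.scores
                sad = saddle_strength(oe, score, q=q, ab_mode=ab_mode)
                strengths_aa.append(sad.strength_aa)
                strengths_bb.append(sad.strength_bb)
                fl, fs = cis_range_fractions(m)
                longs.append(fl)
                shorts.append(fs)
            score_vectors[cond] = svec
            hic_res[cond] = {
                "strength_aa": float(np.mean(strengths_aa)),
                "strength_bb": float(np.mean(strengths_bb)),
                "frac_long": float(np.mean(longs)),
                "frac_short": float(np.mean(shorts)),
            }
        hic_res["shift_counts"] = compartment_shift_counts(
            score_vectors["parental"], score_vectors["treated"]
        )
        results["hic"] = hic_res
        if stage in selected:
            for cond in ("parental", "treated"):
                svals = np.nan_to_num(score_vectors[cond], nan=0.0)
                p = outdir / f"hic.{cond}.scores.bedgraph"
                eio.write_bedgraph(_score_track(layout, hic_bin, svals), p)
                files[f"hic_scores_{cond}"] = p
            p = outdir / "hic.stats.json"
            _jwrite(hic_res, p)
            files["hic_stats"] = p

        stage = "loops"
        lcfg = dict(config.get("loops", {}))
        lost = find_lost_loops(
            loop_sets["parental"], loop_sets["treated"],
            span_cutoff=lcfg.get("span_cutoff", 500_000),
            tolerance_bins=lcfg.get("tolerance_bins", 0),
        )
        assoc, summary = loop_anchor_enhancer_genes(lost, enhancers, genes, deltas)
        results["loops"] = {"n_parental": len(loop_sets["parental"]),
                            "n_treated": len(loop_sets["treated"]),
                            "n_lost": len(lost), **summary}
        if stage in selected:
            p = outdir / "loops.lost.bedpe"
            write_bedpe(lost, p)
            files["loops_lost"] = p
            p = outdir / "loops.association.tsv"
            assoc.to_csv(p, sep="\t", index=False)
            files["loops_association"] = p
            p = outdir / "loops.stats.json"
            _jwrite(results["loops"], p)
            files["loops_stats"] = p

        stage = "report"
        if stage in selected:
            p = outdir / "report.json"
            _jwrite(results, p)
            files["report"] = p
    except Exception as exc:
        raise GenomicsError(f"stage {stage!r} failed: {exc}") from exc

    manifest = eio.write_manifest(
        files, outdir / "manifest.json",
        extra={"seed": master, "stages": sorted(selected & set(STAGES))},
    )
    marker.unlink(missing_ok=True)
    return manifest


def _score_track(layout, bin_size, values):
    from .genome import BinnedTrack as _BT

    return _BT(layout, bin_size, values, "log2ratio")


def write_fixture_bundle(
    outdir, layout, genes, enhancers, truth,
    parental, treated, input_track, cal, matrices, loop_sets, deltas,
) -> dict[str, Path]:
    """Write every simulated object as plain text and return the file map."""
    outdir = Path(outdir)
    files: dict[str, Path] = {}

    p = outdir / "genome.chrom.sizes"
    eio.write_chrom_sizes(layout, p)
    files["chrom_sizes"] = p
    p = outdir / "genes.tsv"
    eio.write_gene_table(genes, p)
    files["genes"] = p
    p = outdir / "genes.bed"
    eio.write_bed(genes.intervals(), p)
    files["genes_bed"] = p
    p = outdir / "enhancers.bed"
    eio.write_bed(enhancers, p, columns=4)
    files["enhancers"] = p
    p = outdir / "domains.planted.bed"
    eio.write_bed(truth.domains, p, columns=4)
    files["domains_planted"] = p
    for name, track in (("parental", parental), ("treated", treated),
                        ("input", input_track)):
        p = outdir / f"{name}.counts.bedgraph"
        eio.write_bedgraph(track, p)
        files[f"counts_{name}"] = p
    p = outdir / "ms_calibration.tsv"
    eio.write_ms_calibration(cal, p)
    files["ms_calibration"] = p
    p = outdir / "expression.tsv"
    eio.write_expression(deltas, p)
    files["expression"] = p
    for cond, per_chrom in matrices.items():
        for chrom, m in per_chrom.items():
            p = outdir / f"contacts.{cond}.{chrom}.coo.tsv"
            write_coo_matrix(m, p)
            files[f"contacts_{cond}_{chrom}"] = p
    for cond, ls in loop_sets.items():
        p = outdir / f"loops.{cond}.bedpe"
        write_bedpe(ls, p)
        files[f"loops_{cond}"] = p
    return files
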