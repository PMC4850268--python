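"""End-to-end driver reproducing the analysis order on simulated data.

Stages: bin -> local-normalize -> diff -> Poisson p-values -> Hochberg ->
call peaks -> exclude negative-control peaks -> annotate and apply the
300-bp filter -> cross-factor comparison and codependence -> expression
classification -> integration -> motif scan.  Every stage writes a TSV so
any stage can be validated or re-run from its predecessor's output, and
the whole run is a deterministic function of the configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import expression as expr
from . import io as rio
from . import motif as mot
from . import peakcall as pc
from . import regulon as reg
from . import simulate as sim
from . import tracks as trk

__all__ = ["PipelineConfig", "factor_analysis", "run_simulated_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis constants: 25-bp bins, alpha 1e-4 on the Hochberg-adjusted
    p-value, 300-bp upstream distance cutoff, 50-base peak-match tolerance,
    401-bin (~10-kb) local-normalization window, and the 16-20 h assessed
    expression timepoints."""

    bin_size: int = 25
    alpha: float = 1e-4
    distance_max: int = 300
    match_tolerance: int = 50
    lnorm_window_bins: int = 401
    rate_window_bins: int = 41
    control_tolerance_bins: int = 2
    max_gap_bins: int = 1
    assessed_timepoints: tuple = (16.0, 18.0, 20.0)
    motif: str = "GACAC"
    motif_window: int = 100
    motif_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bin_size",
            "alpha",
            "distance_max",
            "match_tolerance",
            "lnorm_window_bins",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "assessed_timepoints" in raw:
            raw["assessed_timepoints"] = tuple(raw["assessed_timepoints"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def compute_stats(
    ip: trk.BinnedTrack, input_track: trk.BinnedTrack, cfg: PipelineConfig
) -> pc.BinStats:
    return pc.compute_bin_stats(
        ip,
        input_track,
        lnorm_window_bins=cfg.lnorm_window_bins,
        rate_window_bins=cfg.rate_window_bins,
        alpha=cfg.alpha,
    )


def factor_analysis(
    stats_map: dict,
    control_stats: pc.BinStats | None,
    genes: pd.DataFrame,
    cfg: PipelineConfig,
) -> dict:
    """Peak calling, control exclusion, annotation and distance filter.

    ``stats_map`` maps dataset id -> :class:`~regulomap.peakcall.BinStats`
    for the test IP samples of one factor.  Returns the raw, excluded and
    retained peak tables plus the PeakSet objects for set comparison.
    """
    peaks = pc.call_peaks(stats_map, alpha=cfg.alpha, max_gap_bins=cfg.max_gap_bins)
    if control_stats is not None:
        control_bins = pc.significant_bins(control_stats, cfg.alpha)
        peaks_clean = pc.exclude_control_peaks(
            peaks, control_bins, cfg.control_tolerance_bins
        )
    else:
        control_bins = np.array([], dtype=np.int64)
        peaks_clean = peaks
    annotations = ann.annotate_peaks(peaks_clean.positions, genes, cfg.distance_max)
    retained = ann.filter_retained(annotations)
    return {
        "peaks_raw": peaks,
        "peaks": peaks_clean,
        "control_bins": control_bins,
        "annotations": annotations,
        "retained": retained,
    }


def _write(df: pd.DataFrame, path: Path, stage: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    logger.info("stage %-22s -> %s (%d rows)", stage, path.name, len(df))


def run_simulated_pipeline(
    sim_cfg: sim.SimulationConfig,
    cfg: PipelineConfig,
    outdir,
    write_bin_tables: bool = False,
) -> dict:
    """Simulate a two-factor, multi-genotype experiment and analyze it.

    Samples: for each factor an anti-FLAG IP in the wild type plus IPs in
    the partner-deletion and cluster-variant genotypes, a matched input
    per genotype, and a negative-control IP (untagged strain).  Returns a
    summary dict of the headline numbers; all tables are written under
    ``outdir``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline start: config hash %s, seed %d", cfg.config_hash(), sim_cfg.seed
    )

    # --- synthetic truth -------------------------------------------------
    genome0, genes = sim.generate_genome(sim_cfg)
    sites, genome = sim.plant_sites(genome0, genes, sim_cfg)
    rio.write_fasta(genome.sequence, out / "genome.fasta")
    rio.write_gff3(genes, out / "genes.gff3")
    rio.write_sites_bed(sites, out / "truth_sites.bed")
    logger.info(
        "simulated %d genes, %d sites (%d artifact)",
        len(genes),
        len(sites),
        sum(s.artifact for s in sites),
    )

    genotypes = {
        "wt": sim.WILD_TYPE,
        "dA": sim.DELTA_WHIA,
        "dB": sim.DELTA_WHIB,
        "4cs": sim.FOUR_CS,
    }
    # replicate stream 0 = factor B (the Wbl factor), 1 = factor A (partner)
    samples = {}
    for gname, gt in genotypes.items():
        samples[f"input_{gname}"] = sim.simulate_coverage(
            genome, sites, gt, "input", sim_cfg, 0, f"input_{gname}"
        )
    samples["ipB_wt"] = sim.simulate_coverage(
        genome, sites, sim.WILD_TYPE, "IP", sim_cfg, 0, "ipB_wt"
    )
    samples["ipA_wt"] = sim.simulate_coverage(
        genome, sites, sim.WILD_TYPE, "IP", sim_cfg, 1, "ipA_wt"
    )
    samples["ctrl"] = sim.simulate_coverage(
        genome, sites, sim.WILD_TYPE, "control_IP", sim_cfg, 0, "ctrl"
    )
    samples["ipB_dA"] = sim.simulate_coverage(
        genome, sites, sim.DELTA_WHIA, "IP", sim_cfg, 0, "ipB_dA"
    )
    samples["ipA_dB"] = sim.simulate_coverage(
        genome, sites, sim.DELTA_WHIB, "IP", sim_cfg, 1, "ipA_dB"
    )
    samples["ipB_4cs"] = sim.simulate_coverage(
        genome, sites, sim.FOUR_CS, "IP", sim_cfg, 0, "ipB_4cs"
    )
    for name, track in samples.items():
        trk.write_bedgraph(track, out / f"{name}.bedgraph")

    # --- per-dataset bin statistics -------------------------------------
    matched_input = {
        "ipB_wt": "input_wt",
        "ipA_wt": "input_wt",
        "ctrl": "input_wt",
        "ipB_dA": "input_dA",
        "ipA_dB": "input_dB",
        "ipB_4cs": "input_4cs",
    }
    stats = {
        ds: compute_stats(samples[ds], samples[inp], cfg)
        for ds, inp in matched_input.items()
    }
    if write_bin_tables:
        for ds, st in stats.items():
            _write(st.to_frame(), out / f"{ds}_bins.tsv", f"binstats[{ds}]")

    # --- peak calling, exclusion, annotation ----------------------------
    results = {}
    for ds in ("ipB_wt", "ipA_wt", "ipB_dA", "ipA_dB", "ipB_4cs"):
        results[ds] = factor_analysis({ds: stats[ds]}, stats["ctrl"], genes, cfg)
        _write(results[ds]["peaks"].to_frame(), out / f"peaks_{ds}.tsv", f"peaks[{ds}]")
        _write(
            results[ds]["annotations"], out / f"annotated_{ds}.tsv", f"annotate[{ds}]"
        )
    retained_B = results["ipB_wt"]["retained"]
    _write(retained_B, out / "regulon_ipB_wt.tsv", "regulon[ipB_wt]")

    # --- cross-factor comparison ----------------------------------------
    peaks_B = results["ipB_wt"]["peaks"]
    peaks_A = results["ipA_wt"]["peaks"]
    matched = reg.match_peak_sets(peaks_B, peaks_A, cfg.match_tolerance)
    shared = [m for m in matched if m.status == "shared"]
    shared_fraction = len(shared) / max(len(peaks_B), 1)
    try:
        rho = reg.significance_correlation(
            matched, peaks_B.summit_apv("ipB_wt"), peaks_A.summit_apv("ipA_wt")
        )
    except ValueError:
        rho = float("nan")
    _write(reg.match_table(matched), out / "factor_comparison.tsv", "compare")

    # --- codependence ----------------------------------------------------
    dep_rows, dep_fractions = [], {}
    for mutant in ("ipB_dA", "ipA_dB", "ipB_4cs"):
        wt_ds = "ipA_wt" if mutant == "ipA_dB" else "ipB_wt"
        calls = reg.codependence(
            results[wt_ds]["peaks"], results[mutant]["peaks"], cfg.match_tolerance
        )
        dep_fractions[mutant] = reg.dependent_fraction(calls)
        for c in calls:
            dep_rows.append(
                {
                    "comparison": f"{wt_ds}_vs_{mutant}",
                    "peak_pos": c.peak_pos,
                    "present_mutant": c.present_mutant,
                    "call": c.call,
                }
            )
    _write(pd.DataFrame(dep_rows), out / "codependence.tsv", "depend")

    # --- expression -------------------------------------------------------
    mats = {
        "WT": sim.simulate_expression(genes, sites, sim.WILD_TYPE, sim_cfg, "WT"),
        "dB": sim.simulate_expression(genes, sites, sim.DELTA_WHIB, sim_cfg, "dB"),
    }
    normed = expr.per_gene_normalize(mats)
    for name, m in normed.items():
        expr.write_expression_tsv(m, out / f"expression_{name}.tsv")
    logfc = expr.logfc_profile(normed["dB"], normed["WT"])
    classes = expr.classify_targets(logfc, cfg.assessed_timepoints)
    _write(
        classes.reset_index(names="gene_id"), out / "target_classes.tsv", "classify"
    )
    integrated = expr.integrate(retained_B, classes)
    _write(integrated, out / "integrated.tsv", "integrate")

    # --- motif ------------------------------------------------------------
    if len(retained_B):
        scan = mot.scan_peaks(
            retained_B["peak_pos"].to_numpy(),
            genome.sequence,
            cfg.motif,
            cfg.motif_window,
            cfg.motif_permutations,
            seed=cfg.seed,
        )
        _write(scan.to_frame(), out / "motif.tsv", "motif")
        motif_summary = asdict(scan) if hasattr(scan, "__dict__") else scan.__dict__
    else:
        motif_summary = {
            "motif": cfg.motif,
            "genome_count_both_strands": mot.count_motif(genome.sequence, cfg.motif),
            "n_peaks": 0,
        }

    summary = {
        "n_genes": len(genes),
        "n_sites": sum(not s.artifact for s in sites),
        "n_artifact_sites": sum(s.artifact for s in sites),
        "n_peaks_B": len(peaks_B),
        "n_peaks_A": len(peaks_A),
        "n_retained_B": len(retained_B),
        "shared_fraction": shared_fraction,
        "significance_rank_correlation": rho,
        "dependent_fractions": dep_fractions,
        "class_counts": integrated["class"].value_counts().to_dict(),
        "motif": motif_summary,
        "config_hash": cfg.config_hash(),
        "seed": sim_cfg.seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("pipeline done: %s", json.dumps(summary, default=float)[:300])
    return summary
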