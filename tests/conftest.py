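import numpy as np
import pytest

import regulomap as rm


@pytest.fixture(scope="session")
def study_conditions():
    """Default desk-scale study conditions with a fixed seed."""
    return rm.SimulationConfig(seed=2026)


@pytest.fixture(scope="session")
def sim_bundle(study_conditions):
    """One fully simulated experiment shared by the integration tests.

    Genome + genes + truth sites, wild-type IPs for both factors, matched
    input, negative-control IP, and per-dataset bin statistics.
    """
    cfg = study_conditions
    genome0, genes = rm.generate_genome(cfg)
    sites, genome = rm.plant_sites(genome0, genes, cfg)
    pipe = rm.PipelineConfig(seed=cfg.seed)
    wt = rm.WILD_TYPE
    tracks = {
        "input": rm.simulate_coverage(genome, sites, wt, "input", cfg, 0, "input"),
        "ipB": rm.simulate_coverage(genome, sites, wt, "IP", cfg, 0, "ipB"),
        "ipA": rm.simulate_coverage(genome, sites, wt, "IP", cfg, 1, "ipA"),
        "ctrl": rm.simulate_coverage(genome, sites, wt, "control_IP", cfg, 0, "ctrl"),
    }
    stats = {
        name: rm.compute_bin_stats(
            tracks[name],
            tracks["input"],
            lnorm_window_bins=pipe.lnorm_window_bins,
            rate_window_bins=pipe.rate_window_bins,
            alpha=pipe.alpha,
        )
        for name in ("ipB", "ipA", "ctrl")
    }
    return {
        "config": cfg,
        "pipe": pipe,
        "genome": genome,
        "genes": genes,
        "sites": sites,
        "true_sites": [s for s in sites if not s.artifact],
        "artifact_sites": [s for s in sites if s.artifact],
        "tracks": tracks,
        "stats": stats,
    }


@pytest.fixture(scope="session")
def called_peaks(sim_bundle):
    """Peaks for both factors, before and after control exclusion."""
    pipe = sim_bundle["pipe"]
    control_bins = rm.significant_bins(sim_bundle["stats"]["ctrl"])
    out = {}
    for name in ("ipB", "ipA"):
        raw = rm.call_peaks({name: sim_bundle["stats"][name]}, alpha=pipe.alpha)
        out[name + "_raw"] = raw
        out[name] = rm.exclude_control_peaks(
            raw, control_bins, pipe.control_tolerance_bins
        )
    out["control_bins"] = control_bins
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)
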