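"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a ChIP-seq experiment on a linear, high-GC
bacterial chromosome: a genome with non-overlapping genes on both strands;
binding sites planted in the intergenic region just upstream of target
start codons, each carrying the GACAC consensus 5-mer; coverage tracks in
which the immunoprecipitated (IP) sample is locally enriched at occupied
sites while the input sample records only the nonuniform shearing of the
chromosome; antibody-background artifact sites that appear in every IP
including the negative control; and time-course expression matrices in
which targets are activated or repressed by the factor pair.

Occupancy is codependent: a site is occupied only when both factors are
functional and the iron-sulfur cluster of the Wbl-family partner is
intact (`Genotype.occupancy_allowed`).  Deleting either factor, or
substituting the four cluster-coordinating cysteines (the 4C-S variant),
abolishes all specific binding while leaving artifacts untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import math
import zlib

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .expression import ExpressionMatrix
from .io import GENE_COLUMNS
from .tracks import BinnedTrack, DEFAULT_BIN_SIZE

__all__ = [
    "SimulatedGenome",
    "TruthSite",
    "Genotype",
    "SimulationConfig",
    "WILD_TYPE",
    "DELTA_WHIA",
    "DELTA_WHIB",
    "FOUR_CS",
    "generate_genome",
    "plant_sites",
    "shear_field",
    "expected_coverage",
    "simulate_coverage",
    "simulate_expression",
]

logger = logging.getLogger(__name__)

MOTIF = "GACAC"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# seed-stream tags so every output is an independent, reproducible stream
_TAG_GENOME, _TAG_SITES, _TAG_FIELD, _TAG_COUNTS, _TAG_EXPR_BASE, _TAG_EXPR_NOISE = (
    1, 2, 3, 4, 5, 6,
)

ROLES = ("IP", "input", "control_IP")
_ROLE_CODE = {"ip": 0, "input": 1, "control_ip": 2}


@dataclass
class SimulatedGenome:
    sequence: str
    topology: str = "linear"

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TruthSite:
    """A planted binding site (simulation ground truth).

    Non-artifact sites sit at most 300 bases upstream of their target
    gene's start codon and carry the GACAC motif; artifact sites model
    antibody background present in every IP sample, in every genotype.
    """

    pos: int
    enrichment: float
    target_gene: str | None = None
    mode: str | None = None  # "activated" | "repressed"
    artifact: bool = False


@dataclass(frozen=True)
class Genotype:
    whiA_functional: bool = True
    whiB_functional: bool = True
    cluster_intact: bool = True

    @property
    def occupancy_allowed(self) -> bool:
        return self.whiA_functional and self.whiB_functional and self.cluster_intact

    @property
    def code(self) -> int:
        return (
            (self.whiA_functional << 2)
            | (self.whiB_functional << 1)
            | int(self.cluster_intact)
        )


WILD_TYPE = Genotype()
DELTA_WHIA = Genotype(whiA_functional=False)
DELTA_WHIB = Genotype(whiB_functional=False)
FOUR_CS = Genotype(cluster_intact=False)  # cysteine->serine cluster variant


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults are desk-scale stand-ins for the real system: a 1-Mb slice of
    a ~72% GC chromosome, 50 codependent binding sites (for the ~240 real
    target transcription units), 5 antibody-background loci, mean coverage
    of 30 reads per 25-bp bin, site enrichment 8-15x, and 2-hourly
    expression sampling from 8 to 20 h with a 4-fold (2 log2-unit) target
    effect switching on at 16 h (sporulation onset).
    """

    length: int = 1_000_000
    gc_fraction: float = 0.72
    n_genes: int = 400
    n_sites: int = 50
    n_artifact_sites: int = 5
    mean_depth: float = 30.0
    fragment_sd: int = 150  # half-width (bases) of the triangular site taper
    shear_bias_scale: float = 0.5  # log-sd of the shearing-bias field
    shear_corr_bp: int = 2_000  # autocorrelation bandwidth of the field
    enrichment_range: tuple = (8.0, 15.0)
    timepoints: tuple = (8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0)
    effect_onset_h: float = 16.0
    effect_log2: float = 2.0
    noise_sd: float = 0.3
    bin_size: int = DEFAULT_BIN_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_sites, self.n_artifact_sites) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be ascending")


def _rng(config: SimulationConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed)] + [int(t) for t in tags])


def generate_genome(config: SimulationConfig) -> tuple[SimulatedGenome, pd.DataFrame]:
    """Random genome plus non-overlapping gene models on both strands.

    Gene lengths are uniform on [800, 1200] bases; intergenic gaps share
    the remaining length (seeded multinomial), so packing fails loudly
    when ``n_genes`` genes cannot fit.
    """
    if config.length < 10_000:
        raise ValueError("genome length must be >= 10,000 bases")
    if config.n_genes * 1_200 > config.length:
        raise ValueError(
            f"cannot pack {config.n_genes} genes of up to 1.2 kb "
            f"into {config.length} bases"
        )
    rng = _rng(config, _TAG_GENOME)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=config.length, p=probs)
    sequence = np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")

    n = config.n_genes
    if n == 0:
        genes = pd.DataFrame(columns=GENE_COLUMNS)
        return SimulatedGenome(sequence), genes

    lengths = rng.integers(800, 1_201, size=n)
    slack = config.length - int(lengths.sum())
    if slack < 0:
        raise ValueError("infeasible packing: gene lengths exceed genome length")
    min_gap = min(150, slack // (n + 1))
    extra = slack - min_gap * (n + 1)
    gaps = rng.multinomial(extra, np.full(n + 1, 1.0 / (n + 1))) + min_gap
    strands = rng.choice(["+", "-"], size=n)
    starts = np.empty(n, dtype=np.int64)
    pos = 0
    for i in range(n):
        pos += gaps[i]
        starts[i] = pos + 1  # 1-based
        pos += lengths[i]
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n)],
            "start": starts,
            "end": starts + lengths - 1,
            "strand": strands,
            "product": "hypothetical protein",
        }
    )
    return SimulatedGenome(sequence), genes


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def plant_sites(
    genome: SimulatedGenome,
    genes: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[list[TruthSite], SimulatedGenome]:
    """Place codependent binding sites upstream of distinct target genes.

    Each non-artifact site center lies 60-300 bases upstream of its
    target's start codon, inside the intergenic region, and the GACAC
    consensus (randomly oriented) is written into the returned genome at
    the site.  Modes alternate activated/repressed.  Artifact sites are
    placed anywhere, at least 500 bases away from true sites.
    """
    if config.n_sites > len(genes):
        raise ValueError("n_sites exceeds number of genes")
    rng = _rng(config, _TAG_SITES)
    L = genome.length
    seq = bytearray(genome.sequence, "ascii")

    starts = genes["start"].to_numpy() if len(genes) else np.array([], dtype=int)
    ends = genes["end"].to_numpy() if len(genes) else np.array([], dtype=int)
    windows: list[tuple[int, int, int]] = []  # (gene_index, lo, hi) for site center
    skipped = 0
    for i in range(len(genes)):
        strand = genes.at[i, "strand"]
        if strand == "+":
            prev_end = int(ends[i - 1]) if i > 0 else 0
            room = int(starts[i]) - 1 - prev_end
            lo = max(int(starts[i]) - 300, prev_end + 3)
            hi = int(starts[i]) - 60
        else:
            next_start = int(starts[i + 1]) if i + 1 < len(genes) else L + 1
            room = next_start - 1 - int(ends[i])
            lo = int(ends[i]) + 60
            hi = min(int(ends[i]) + 300, next_start - 3)
        if room < 20 or hi < lo:
            skipped += 1
            continue
        windows.append((i, lo, hi))
    if skipped:
        logger.warning(
            "%d genes lack >= 20 bases of upstream intergenic room and were skipped",
            skipped,
        )
    if config.n_sites > len(windows):
        raise ValueError(
            f"only {len(windows)} genes have upstream room for a site; "
            f"cannot plant {config.n_sites}"
        )

    sites: list[TruthSite] = []
    if config.n_sites > 0:
        chosen = rng.choice(len(windows), size=config.n_sites, replace=False)
        lo_e, hi_e = config.enrichment_range
        for k, w in enumerate(sorted(chosen, key=lambda j: windows[j][1])):
            gi, lo, hi = windows[w]
            pos = int(rng.integers(lo, hi + 1))
            enrichment = float(rng.uniform(lo_e, hi_e))
            mode = "activated" if k % 2 == 0 else "repressed"
            motif = MOTIF if rng.random() < 0.5 else _reverse_complement(MOTIF)
            seq[pos - 3 : pos + 2] = motif.encode("ascii")
            sites.append(
                TruthSite(
                    pos=pos,
                    enrichment=enrichment,
                    target_gene=genes.at[gi, "gene_id"],
                    mode=mode,
                )
            )

    true_pos = np.array([s.pos for s in sites], dtype=np.int64)
    placed: list[int] = []
    for _ in range(config.n_artifact_sites):
        for _attempt in range(1000):
            pos = int(rng.integers(200, L - 200))
            near_true = true_pos.size and np.min(np.abs(true_pos - pos)) < 500
            near_art = placed and min(abs(p - pos) for p in placed) < 500
            if not near_true and not near_art:
                break
        else:  # pragma: no cover - pathological packing
            raise RuntimeError("could not place artifact site away from true sites")
        placed.append(pos)
        lo_e, hi_e = config.enrichment_range
        sites.append(
            TruthSite(pos=pos, enrichment=float(rng.uniform(lo_e, hi_e)), artifact=True)
        )

    sites.sort(key=lambda s: s.pos)
    return sites, SimulatedGenome(seq.decode("ascii"), genome.topology)


def _genome_length(genome) -> int:
    return genome if isinstance(genome, (int, np.integer)) else genome.length


def shear_field(genome, config: SimulationConfig) -> np.ndarray:
    """Smooth positive shearing-bias field, one value per bin.

    Log-normal with Gaussian-kernel autocorrelation (bandwidth
    ``shear_corr_bp``), unit mean on the log-normal scale, clipped to
    [0.2, 5].  The field is a property of the simulated chromosome
    (seeded by ``config.seed`` alone), so it is shared by the IP sample,
    its matched input, and every other sample drawn from the same genome.
    """
    n_bins = math.ceil(_genome_length(genome) / config.bin_size)
    sd = config.shear_bias_scale
    if sd <= 0 or n_bins < 2:
        return np.ones(n_bins)
    rng = _rng(config, _TAG_FIELD)
    z = rng.standard_normal(n_bins)
    sigma_bins = max(config.shear_corr_bp / config.bin_size, 1.0)
    z = gaussian_filter1d(z, sigma_bins, mode="nearest")
    z = z / z.std() * sd - sd**2 / 2
    return np.clip(np.exp(z), 0.2, 5.0)


def _site_applies(site: TruthSite, role: str, genotype: Genotype) -> bool:
    if site.artifact:
        return role in ("ip", "control_ip")
    return role == "ip" and genotype.occupancy_allowed


def expected_coverage(
    genome,
    sites,
    genotype: Genotype,
    role: str,
    config: SimulationConfig,
) -> np.ndarray:
    """Per-bin Poisson expectation for one sample.

    Baseline is ``mean_depth`` times the shearing field.  For occupied
    (or artifact) sites the expectation within ``fragment_sd`` bases of
    the site center is multiplied by the site's enrichment under a
    triangular taper, mimicking fragment pile-up without a read model.
    """
    role_key = role.lower()
    if role_key not in _ROLE_CODE:
        raise ValueError(f"role must be one of {ROLES}")
    L = _genome_length(genome)
    expectation = config.mean_depth * shear_field(genome, config)
    n_bins = expectation.shape[0]
    starts = np.arange(n_bins, dtype=np.int64) * config.bin_size
    centers = (starts + 1 + np.minimum(starts + config.bin_size, L)) // 2
    half = config.fragment_sd
    for site in sites:
        if not _site_applies(site, role_key, genotype):
            continue
        lo = np.searchsorted(centers, site.pos - half)
        hi = np.searchsorted(centers, site.pos + half, side="right")
        if hi <= lo:
            continue
        d = np.abs(centers[lo:hi] - site.pos)
        taper = np.clip(1.0 - d / half, 0.0, 1.0)
        expectation[lo:hi] *= 1.0 + (site.enrichment - 1.0) * taper
    return expectation


def simulate_coverage(
    genome,
    sites,
    genotype: Genotype,
    role: str,
    config: SimulationConfig,
    replicate: int = 0,
    sample_id: str = "",
) -> BinnedTrack:
    """Draw one sample's binned counts: Poisson around the expectation.

    ``replicate`` separates the counting-noise streams of samples that
    share a role and genotype (for example the two factors' anti-FLAG IPs,
    which probe the same truth independently).
    """
    expectation = expected_coverage(genome, sites, genotype, role, config)
    rng = _rng(
        config, _TAG_COUNTS, _ROLE_CODE[role.lower()], genotype.code, replicate
    )
    counts = rng.poisson(expectation).astype(float)
    return BinnedTrack(
        counts,
        _genome_length(genome),
        config.bin_size,
        sample_id or f"{role}_{genotype.code}_{replicate}",
    )


def simulate_expression(
    genes: pd.DataFrame,
    sites,
    genotype: Genotype,
    config: SimulationConfig,
    strain: str = "WT",
) -> ExpressionMatrix:
    """Log2 expression (gene x timepoint) for one strain.

    Every gene has a genotype-independent constant baseline.  Target genes
    of non-artifact sites shift by ``effect_log2`` from ``effect_onset_h``
    onwards — upwards for activated targets, downwards for repressed —
    but only in genotypes in which the factors can occupy their sites.
    Gaussian noise (sd ``noise_sd``) is independent across strains.
    """
    timepoints = np.asarray(config.timepoints, dtype=float)
    n_genes, n_t = len(genes), timepoints.size
    base_rng = _rng(config, _TAG_EXPR_BASE)
    levels = base_rng.normal(7.0, 1.0, size=n_genes)
    values = np.tile(levels[:, None], (1, n_t))

    if genotype.occupancy_allowed:
        mode_by_gene = {
            s.target_gene: s.mode for s in sites if not s.artifact and s.target_gene
        }
        late = timepoints >= config.effect_onset_h
        gene_ids = genes["gene_id"].tolist()
        for i, gid in enumerate(gene_ids):
            mode = mode_by_gene.get(gid)
            if mode == "activated":
                values[i, late] += config.effect_log2
            elif mode == "repressed":
                values[i, late] -= config.effect_log2

    if config.noise_sd > 0:
        noise_rng = _rng(
            config, _TAG_EXPR_NOISE, zlib.crc32(strain.encode()), genotype.code
        )
        values = values + noise_rng.normal(0.0, config.noise_sd, size=values.shape)

    data = pd.DataFrame(values, index=genes["gene_id"].tolist(), columns=timepoints)
    return ExpressionMatrix(data, strain=strain)
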