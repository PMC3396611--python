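"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a 136-patient archival-tissue breast-cancer cohort
profiled genome-wide by RNA-seq:

* per-feature abundance spread over the four median-count bins (<10, 10-99,
  100-999, >=1000) in the proportions observed in the real cohort;
* negative-binomial counts around a block-correlated latent log-normal
  expression layer (the blocks emulate co-expressed gene networks) with
  per-sample library-size variation;
* exponential survival whose log hazard is a linear combination of the
  standardized latent expression of a minority of truly prognostic features,
  with administrative censoring calibrated numerically so the expected number
  of events hits a target (26 of 136 in the emulated cohort);
* a small synthetic genome (genes as refFlat records plus hidden transcribed
  intergenic loci) over which 50-bp reads are sampled, for exercising the
  intergenic-discovery pipeline end to end.

Everything is driven by one integer seed; identical configs and seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .io_formats import CountMatrix, GenomicInterval, RefFlatRecord, SurvivalRecord

# Realized-median bin edges used throughout (half-open [lo, hi)).
ABUNDANCE_BINS: tuple[tuple[str, float, float], ...] = (
    ("<10", 1.0, 10.0),
    ("10-99", 10.0, 100.0),
    ("100-999", 100.0, 1000.0),
    (">=1000", 1000.0, 10000.0),
)
# Default mix: the real cohort's 20,462 retained features split 5817 / 6245 /
# 7657 / 743 across the four bins.
DEFAULT_ABUNDANCE_MIX: tuple[tuple[str, float], ...] = (
    ("<10", 5817 / 20462),
    ("10-99", 6245 / 20462),
    ("100-999", 7657 / 20462),
    (">=1000", 743 / 20462),
)


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``log_hazard_sd`` scales the true per-SD log-hazard effects (drawn
    N(0, log_hazard_sd^2)) of the prognostic minority; ``nb_dispersion`` is
    the extra-Poisson technical dispersion alpha in Var = mu + alpha mu^2 (the
    biological variation lives in the latent log-normal layer, SD
    ``latent_sd`` on the natural-log scale); ``libsize_cv`` is the
    coefficient of variation of per-sample library-size factors;
    ``censor_rate`` optionally censors that fraction of patients uniformly
    early, before the administrative cutoff is calibrated to
    ``n_events_target``.

    Prognostic features are assigned block-first: whole co-expression blocks
    become prognostic before isolated singletons are added, mirroring real
    tumor cohorts where prognosis-associated transcripts arrive as correlated
    programs (cell-cycle, hormone-receptor networks) rather than as thousands
    of independent signals. The structural effects are rescaled, if needed, so
    the cohort SD of the total log-hazard linear predictor does not exceed
    ``prognostic_index_sd``; without this cap, summing hundreds of independent
    effects produces astronomically heterogeneous hazards in which no single
    feature retains a detectable marginal association.
    """

    n_patients: int = 136
    n_features: int = 20000
    n_events_target: int = 26
    prognostic_fraction: float = 0.10
    log_hazard_sd: float = 0.50
    nb_dispersion: float = 0.05
    abundance_mix: tuple[tuple[str, float], ...] = DEFAULT_ABUNDANCE_MIX
    libsize_cv: float = 0.3
    block_sizes: tuple[int, ...] = (10, 10, 20, 25, 50)
    block_rho: float = 0.8
    censor_rate: float = 0.0
    latent_sd: float = 0.8
    baseline_hazard: float = 0.002  # per month
    prognostic_index_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prognostic_fraction", "libsize_cv", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.block_rho < 1.0:
            raise ConfigurationError(f"block_rho must lie in [0, 1), got {self.block_rho}")
        if self.nb_dispersion <= 0:
            raise ConfigurationError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        names = [b[0] for b in self.abundance_mix]
        if set(names) - {b[0] for b in ABUNDANCE_BINS}:
            raise ConfigurationError(f"unknown abundance bins in {names}")
        total = sum(p for _, p in self.abundance_mix)
        if any(p < 0 for _, p in self.abundance_mix) or abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"abundance_mix proportions must sum to 1 (got {total})")
        if sum(self.block_sizes) > self.n_features:
            raise ConfigurationError("block_sizes exceed n_features")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigurationError("config must set an explicit seed")
        if "abundance_mix" in raw:
            raw["abundance_mix"] = tuple((str(k), float(v)) for k, v in raw["abundance_mix"])
        if "block_sizes" in raw:
            raw["block_sizes"] = tuple(int(b) for b in raw["block_sizes"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["abundance_mix"] = [list(x) for x in self.abundance_mix]
        d["block_sizes"] = list(self.block_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def calibrate_censor_time(
    rates: np.ndarray, n_events_target: int, lo: float = 1e-6, hi: float = 1e8
) -> float:
    """Administrative cutoff c with expected events sum_j (1 - exp(-rate_j c))
    equal to the target."""
    target = float(n_events_target)
    if target >= len(rates):
        raise ConfigurationError("n_events_target must be < n_patients")

    def expected(c: float) -> float:
        return float(np.sum(1.0 - np.exp(-rates * c))) - target

    return float(brentq(expected, lo, hi, maxiter=200))


def simulate_cohort(
    config: CohortConfig,
) -> tuple[CountMatrix, list[SurvivalRecord], pd.DataFrame]:
    """Generate (counts, survival, truth table) for one cohort.

    The truth table (one row per feature) records the assigned abundance bin
    and target median, block membership, and each feature's true standardized
    log hazard (0 for the non-prognostic majority).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_patients, config.n_features

    # --- abundance: per-feature target median counts ---------------------
    bin_by_name = {b[0]: b for b in ABUNDANCE_BINS}
    names = [b[0] for b in config.abundance_mix]
    probs = np.array([p for _, p in config.abundance_mix])
    counts_per_bin = rng.multinomial(m, probs)
    bin_assign = np.repeat(np.arange(len(names)), counts_per_bin)
    medians = np.empty(m)
    for i, name in enumerate(names):
        _, lo, hi = bin_by_name[name]
        # stay 5% (log-scale) inside the bin so realized medians bin crisply
        llo, lhi = np.log(lo), np.log(hi)
        margin = 0.05 * (lhi - llo)
        k = counts_per_bin[i]
        medians[bin_assign == i] = np.exp(rng.uniform(llo + margin, lhi - margin, size=k))

    # --- latent Gaussian with correlated blocks ---------------------------
    latent = rng.standard_normal((m, n))
    block_id = np.full(m, -1, dtype=int)
    # blocks are planted on well-expressed features (target median >= 50) so
    # that count noise does not swamp the planted correlation
    eligible = np.flatnonzero(medians >= 50.0)
    rng.shuffle(eligible)
    pos = 0
    for b, size in enumerate(config.block_sizes):
        members = eligible[pos : pos + size]
        pos += size
        shared = rng.standard_normal(n)
        r = config.block_rho
        latent[members] = np.sqrt(r) * shared[None, :] + np.sqrt(1 - r) * latent[members]
        block_id[members] = b

    # --- library sizes and NB counts --------------------------------------
    if config.libsize_cv > 0:
        sigma = np.sqrt(np.log1p(config.libsize_cv**2))
        libsize = np.exp(rng.normal(-sigma**2 / 2, sigma, size=n))
    else:
        libsize = np.ones(n)
    mu = medians[:, None] * libsize[None, :] * np.exp(config.latent_sd * latent)
    r_nb = 1.0 / config.nb_dispersion
    # NB as Poisson-gamma mixture keeps the draw vectorized
    lam = rng.gamma(shape=r_nb, scale=mu / r_nb)
    counts = rng.poisson(lam).astype(np.int64)

    # --- survival ----------------------------------------------------------
    n_prog = int(round(config.prognostic_fraction * m))
    beta_struct = np.zeros(m)  # structural coefficients on latent expression
    if n_prog:
        chosen: list[int] = []
        block_order = rng.permutation(len(config.block_sizes))
        for b in block_order:
            members = np.flatnonzero(block_id == b)
            if len(chosen) + len(members) <= n_prog:
                chosen.extend(members.tolist())
        # singletons come from outside every block so partially-prognostic
        # blocks (whose correlated members would inherit marginal effects)
        # never arise
        pool = np.flatnonzero(block_id < 0)
        extra = rng.choice(pool, size=min(n_prog - len(chosen), pool.size), replace=False)
        prog = np.concatenate([np.array(chosen, dtype=int), extra]).astype(int)
        beta_struct[prog] = rng.normal(0.0, config.log_hazard_sd, size=n_prog)
        # cap the prognostic-index spread: Var(eta) = b'Sigma b with
        # within-block latent correlation rho
        var_eta = float(np.sum(beta_struct**2))
        for b in range(len(config.block_sizes)):
            bb = beta_struct[block_id == b]
            var_eta += config.block_rho * (bb.sum() ** 2 - np.sum(bb**2))
        if var_eta > config.prognostic_index_sd**2:
            beta_struct *= config.prognostic_index_sd / np.sqrt(var_eta)
    # marginal per-SD log hazard: Cov(z_f, eta); within a block every member
    # picks up rho times the other members' effects
    beta = beta_struct.copy()
    for b in range(len(config.block_sizes)):
        members = np.flatnonzero(block_id == b)
        if members.size:
            s = beta_struct[members].sum()
            beta[members] += config.block_rho * (s - beta_struct[members])
    z_latent = (latent - latent.mean(axis=1, keepdims=True)) / np.where(
        latent.std(axis=1, ddof=1)[:, None] > 0, latent.std(axis=1, ddof=1)[:, None], 1.0
    )
    eta = beta_struct @ z_latent
    rates = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rates)
    cutoff = calibrate_censor_time(rates, config.n_events_target)
    time = np.minimum(t_event, cutoff)
    event = (t_event <= cutoff).astype(int)
    if config.censor_rate > 0:
        dropout = rng.random(n) < config.censor_rate
        t_drop = rng.uniform(0, cutoff, size=n)
        early = dropout & (t_drop < time)
        time = np.where(early, t_drop, time)
        event = np.where(early, 0, event)

    sample_ids = [f"P{j + 1:03d}" for j in range(n)]
    feature_ids = [f"F{i + 1:05d}" for i in range(m)]
    cm = CountMatrix(
        values=pd.DataFrame(counts, index=feature_ids, columns=sample_ids),
        feature_class="refseq",
    )
    survival = [
        SurvivalRecord(sid, float(max(t, 1e-6)), int(e))
        for sid, t, e in zip(sample_ids, time, event)
    ]
    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "true_beta": beta,
            "prognostic": beta != 0.0,
            "target_median": medians,
            "abundance_bin": [names[i] for i in bin_assign],
            "block_id": block_id,
        }
    ).set_index("feature_id")
    return cm, survival, truth


# ---------------------------------------------------------------------------
# Synthetic genome and reads
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    """Chromosome sizes, gene models, and hidden transcribed intergenic loci.

    ``locus_expression`` holds per-locus, per-patient relative expression
    levels (rows align with ``hidden_loci``); genes carry a single relative
    expression each in ``gene_expression``.
    """

    chrom_sizes: dict[str, int]
    genes: list[RefFlatRecord]
    hidden_loci: list[GenomicInterval]
    gene_expression: np.ndarray = field(default_factory=lambda: np.array([]))
    locus_expression: np.ndarray = field(default_factory=lambda: np.array([[]]))

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.tx_end > self.chrom_sizes.get(g.chrom, 0):
                raise ConfigurationError(f"gene {g.name} exceeds chromosome {g.chrom} bounds")
        spans = sorted((g.chrom, g.tx_start, g.tx_end) for g in self.genes)
        for locus in self.hidden_loci:
            if locus.end > self.chrom_sizes.get(locus.chrom, 0):
                raise ConfigurationError(f"hidden locus {locus} exceeds chromosome bounds")
            for chrom, s, e in spans:
                if chrom == locus.chrom and locus.start < e and s < locus.end:
                    raise ConfigurationError(f"hidden locus {locus} overlaps gene span [{s},{e})")


def make_synthetic_genome(
    seed: int,
    n_patients: int = 8,
    n_chroms: int = 2,
    chrom_size: int = 300_000,
    n_genes: int = 24,
    n_hidden: int = 16,
    hidden_length_range: tuple[int, int] = (300, 1500),
    min_gap: int = 3000,
) -> SyntheticGenome:
    """Lay out non-overlapping genes and hidden intergenic loci on small
    chromosomes, with lognormal relative expression levels."""
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_size for i in range(n_chroms)}
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}

    def try_place(chrom: str, length: int) -> tuple[int, int] | None:
        for _ in range(200):
            start = int(rng.integers(min_gap, chrom_sizes[chrom] - length - min_gap))
            end = start + length
            if all(start - min_gap >= e or s >= end + min_gap for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                return start, end
        return None

    genes: list[RefFlatRecord] = []
    chroms = list(chrom_sizes)
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        span = int(rng.integers(2000, 10000))
        pos = try_place(chrom, span)
        if pos is None:
            continue
        start, end = pos
        n_exons = int(rng.integers(2, 6))
        cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * n_exons, replace=False))
        exon_starts = tuple(int(c) for c in cuts[0::2])
        exon_ends = tuple(int(c) for c in cuts[1::2])
        genes.append(
            RefFlatRecord(
                gene_name=f"GENE{i + 1}",
                name=f"NM_{i + 1:06d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                tx_start=start,
                tx_end=end,
                cds_start=start,
                cds_end=end,
                exon_count=n_exons,
                exon_starts=(start,) + exon_starts[1:],
                exon_ends=exon_ends[:-1] + (end,),
            )
        )
    hidden: list[GenomicInterval] = []
    for i in range(n_hidden):
        chrom = chroms[i % len(chroms)]
        length = int(rng.integers(*hidden_length_range))
        pos = try_place(chrom, length)
        if pos is None:
            continue
        hidden.append(GenomicInterval(chrom, pos[0], pos[1], count=0, label=f"HIDDEN{i + 1}"))
    gene_expr = np.exp(rng.normal(0.0, 0.4, size=len(genes)))
    locus_expr = np.exp(rng.normal(0.0, 0.3, size=(len(hidden), n_patients)))
    return SyntheticGenome(chrom_sizes, genes, hidden, gene_expr, locus_expr)


def simulate_reads(
    genome: SyntheticGenome,
    n_patients: int,
    depth_scale: float,
    seed: int,
    read_length: int = 50,
) -> list[GenomicInterval]:
    """Sample 50-bp reads along expressed gene exons and hidden loci.

    Per patient and locus the read number is Poisson with mean
    depth_scale * expression * length / read_length; read starts are uniform
    within the locus and clipped so no read extends past the chromosome end.
    Read ``label`` carries the patient ID. depth_scale = 0 yields no reads.
    """
    if depth_scale < 0:
        raise ConfigurationError("depth_scale must be >= 0")
    if not genome.genes and not genome.hidden_loci:
        raise ConfigurationError("empty genome: nothing to sample reads from")
    rng = np.random.default_rng(seed)
    reads: list[GenomicInterval] = []
    patients = [f"P{j + 1:03d}" for j in range(n_patients)]

    def sample_from(chrom: str, start: int, end: int, mean_reads: float, patient: str) -> None:
        k = rng.poisson(mean_reads)
        if k == 0:
            return
        hi = max(start + 1, end - read_length + 1)
        starts = rng.integers(start, hi, size=k)
        limit = genome.chrom_sizes[chrom]
        for s in starts:
            e = min(int(s) + read_length, limit)
            reads.append(GenomicInterval(chrom, int(s), e, count=1, label=patient))

    for j, pat in enumerate(patients):
        for gi, gene in enumerate(genome.genes):
            expr = genome.gene_expression[gi] if genome.gene_expression.size else 1.0
            for es, ee in zip(gene.exon_starts, gene.exon_ends):
                mean = depth_scale * expr * (ee - es) / read_length
                sample_from(gene.chrom, es, ee, mean, pat)
        for li, locus in enumerate(genome.hidden_loci):
            expr = (
                genome.locus_expression[li, j % genome.locus_expression.shape[1]]
                if genome.locus_expression.size
                else 1.0
            )
            mean = depth_scale * expr * locus.length / read_length
            sample_from(locus.chrom, locus.start, locus.end, mean, pat)
    reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.label))
    return reads


def simulate_two_platform(
    true_log_hr: np.ndarray, noise_sd_a: float, noise_sd_b: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent noisy measurements of the same true per-feature log
    hazard ratios, for exercising concordance statistics."""
    if noise_sd_a < 0 or noise_sd_b < 0:
        raise ConfigurationError("noise SDs must be >= 0")
    truth = np.asarray(true_log_hr, dtype=float)
    rng = np.random.default_rng(seed)
    a = truth + rng.normal(0.0, noise_sd_a, size=truth.shape)
    b = truth + rng.normal(0.0, noise_sd_b, size=truth.shape)
    return a, b
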