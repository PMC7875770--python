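"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of (config, seed): mixture-distributed
inter-singleton distances with known labels, coalescent singletons under
encoded demographic histories, genotype matrices with group-structured
rare-variant sharing, gene tables with length-dependent pLOF counts, and
negative-binomial window counts driven by feature covariates.

Demographic models
------------------
``ooa_afr_eur``   African-European out-of-Africa history with strong recent
                  exponential growth (coalescent parameterization of
                  Tennessen et al. 2012, Science; generation time 25 y).
                  This is the default for the singleton-clustering
                  baseline.
``ooa_3pop``      Three-population out-of-Africa history (Gutenkunst et
                  al. 2009, PLoS Genetics).
``constant``      Single panmictic population of constant size, the
                  analytic control: the expected number of singletons in a
                  sample is 4*Ne*mu*L, independent of sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

#: Representative four-component mixture of inter-singleton distances:
#: weights and mean distances (bp) for the very-short-range mutational
#: cluster process, the kb-scale C>G-enriched process, and the two
#: near-uniform background processes.
PAPERLIKE_PRESET = {
    "lam": (0.015, 0.18, 0.465, 0.34),
    "theta": (5.0, 2_000.0, 40_000.0, 150_000.0),
}

MUTATION_RATE = 1.29e-8      # per site per generation
RECOMBINATION_RATE = 1e-8    # uniform stand-in for a genetic map


@dataclass
class CoalescentConfig:
    sequence_length: float = 2e7
    mutation_rate: float = MUTATION_RATE
    recombination_rate: float = RECOMBINATION_RATE
    demography: str = "ooa_afr_eur"
    #: diploid individuals per population (keys must exist in the model)
    samples: dict = field(default_factory=lambda: {"EUR": 1000, "AFR": 1000})
    ne: float = 1e4  # only for the constant model


def ooa_afr_eur_demography() -> msprime.Demography:
    """African-European out-of-Africa model (Tennessen et al. 2012).

    Epochs, backward in time: accelerated growth in both populations over
    the last ~5.1 ky; earlier European growth from the bottleneck; the
    out-of-Africa bottleneck and split; African expansion; ancestral size.
    """
    T_AF, T_B, T_EU0, T_EG = 5920.0, 2040.0, 920.0, 205.0
    N_A, N_AF0, N_B, N_EU0 = 7310, 14474, 1861, 1032
    r_EU0, r_EU, r_AF = 0.00307, 0.0195, 0.0166
    N_EU1 = N_EU0 * math.exp(r_EU0 * (T_EU0 - T_EG))
    d = msprime.Demography()
    d.add_population(name="AFR", initial_size=N_AF0 * math.exp(r_AF * T_EG),
                     growth_rate=r_AF, initially_active=True)
    d.add_population(name="EUR", initial_size=N_EU1 * math.exp(r_EU * T_EG),
                     growth_rate=r_EU)
    d.set_symmetric_migration_rate(["AFR", "EUR"], 2.5e-5)
    d.add_population_parameters_change(time=T_EG, population="AFR",
                                       initial_size=N_AF0, growth_rate=0)
    d.add_population_parameters_change(time=T_EG, population="EUR",
                                       initial_size=N_EU1, growth_rate=r_EU0)
    d.add_population_parameters_change(time=T_EU0, population="EUR",
                                       initial_size=N_B, growth_rate=0)
    d.add_symmetric_migration_rate_change(time=T_EU0,
                                          populations=["AFR", "EUR"],
                                          rate=15e-5)
    d.add_population_split(time=T_B, derived=["EUR"], ancestral="AFR")
    d.add_population_parameters_change(time=T_B, population="AFR",
                                       initial_size=N_AF0)
    d.add_population_parameters_change(time=T_AF, population="AFR",
                                       initial_size=N_A)
    d.sort_events()
    return d


def ooa_3pop_demography() -> msprime.Demography:
    """Three-population out-of-Africa model (Gutenkunst et al. 2009)."""
    T_AF, T_B, T_EU_AS = 8800.0, 5600.0, 848.0
    r_EU, r_AS = 0.004, 0.0055
    N_A, N_AF, N_B = 7300, 12300, 2100
    N_EU0, N_AS0 = 1000, 510
    d = msprime.Demography()
    d.add_population(name="AFR", initial_size=N_AF, initially_active=True)
    d.add_population(name="EUR", initial_size=N_EU0 * math.exp(r_EU * T_EU_AS),
                     growth_rate=r_EU)
    d.add_population(name="EAS", initial_size=N_AS0 * math.exp(r_AS * T_EU_AS),
                     growth_rate=r_AS)
    d.add_population(name="OOA", initial_size=N_B)
    d.add_population(name="ANC", initial_size=N_AF)
    d.set_symmetric_migration_rate(["AFR", "EUR"], 3e-5)
    d.set_symmetric_migration_rate(["AFR", "EAS"], 1.9e-5)
    d.set_symmetric_migration_rate(["EUR", "EAS"], 9.6e-5)
    d.add_population_split(time=T_EU_AS, derived=["EUR", "EAS"],
                           ancestral="OOA")
    d.add_symmetric_migration_rate_change(time=T_EU_AS,
                                          populations=["AFR", "OOA"],
                                          rate=25e-5)
    d.add_population_split(time=T_B, derived=["AFR", "OOA"], ancestral="ANC")
    d.add_population_parameters_change(time=T_AF, population="ANC",
                                       initial_size=N_A)
    d.sort_events()
    return d


def get_demography(config: CoalescentConfig) -> msprime.Demography:
    if config.demography == "ooa_afr_eur":
        return ooa_afr_eur_demography()
    if config.demography == "ooa_3pop":
        return ooa_3pop_demography()
    if config.demography == "constant":
        d = msprime.Demography()
        d.add_population(name="pop0", initial_size=config.ne)
        return d
    raise ValueError(f"unknown demographic model {config.demography!r}")


def simulate_mixture_distances(preset=None, n: int = 10_000,
                               seed: int | None = None):
    """Draw labelled distances from an exponential mixture.

    Returns (distances, labels); labels are 1-based component indices.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    preset = preset or PAPERLIKE_PRESET
    lam = np.asarray(preset["lam"], dtype=float)
    theta = np.asarray(preset["theta"], dtype=float)
    if not np.isclose(lam.sum(), 1.0):
        raise ValueError("preset weights must sum to 1")
    if np.any(theta <= 0):
        raise ValueError("preset scales must be positive")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(lam), size=n, p=lam) + 1
    distances = rng.exponential(theta[labels - 1])
    return distances, labels


def simulate_coalescent_singletons(config: CoalescentConfig | None = None,
                                   seed: int = 1) -> dict:
    """Coalescent singletons per diploid, with haploids paired at random.

    Simulates the configured demography, then for each population defines
    singletons *within that population's haplotype sample* (derived allele
    on exactly one of its haplotypes — the in-sample analogue of a
    subsample singleton; an allele shared with the other population still
    counts).  Haplotypes are paired uniformly at random into diploids and
    each singleton is credited to its carrier's diploid, ignoring the
    haplotype of origin.

    Returns ``{"diploids": DataFrame(diploid_id, population, pos),
    "n_sites": int}``.
    """
    config = config or CoalescentConfig()
    if any(v < 1 for v in config.samples.values()):
        raise ValueError("need at least one diploid per sampled population")
    ts = msprime.sim_ancestry(
        samples=dict(config.samples), demography=get_demography(config),
        sequence_length=config.sequence_length,
        recombination_rate=config.recombination_rate,
        random_seed=seed, ploidy=2,
    )
    ts = msprime.sim_mutations(ts, rate=config.mutation_rate,
                               random_seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    pop_names = {p.id: p.metadata.get("name", str(p.id))
                 for p in ts.populations()}
    pop_of = np.array([ts.node(u).population for u in ts.samples()])

    frames = []
    next_dip = 0
    for pid in np.unique(pop_of):
        sub = ts.samples()[pop_of == pid]
        pos, car = _marginal_singletons(ts, sub)
        perm = rng.permutation(sub)
        dip_of = {int(s): next_dip + i // 2 for i, s in enumerate(perm)}
        next_dip += len(sub) // 2
        frames.append(pd.DataFrame({
            "diploid_id": [dip_of[int(c)] for c in car],
            "population": pop_names[int(pid)],
            "pos": pos.astype(np.int64),
        }))
    return {"diploids": pd.concat(frames, ignore_index=True),
            "n_sites": ts.num_sites}


def _marginal_singletons(ts, sample_subset):
    """Sites whose derived allele sits on exactly one subset haplotype.

    Sites carrying more than one mutation (recurrent hits on the discrete
    genome) are skipped: their carrier set is not a clean subtree.
    """
    tracked = np.asarray(sample_subset, dtype=np.int32)
    tset = set(int(s) for s in tracked)
    pos_list, carrier = [], []
    tree = ts.first(tracked_samples=tracked, sample_lists=True)
    for site in ts.sites():
        if len(site.mutations) != 1:
            continue
        mut = site.mutations[0]
        while tree.interval.right <= site.position:
            tree.next()
        if tree.num_tracked_samples(mut.node) == 1:
            c = next(s for s in tree.samples(mut.node) if s in tset)
            pos_list.append(site.position)
            carrier.append(c)
    return np.array(pos_list, dtype=float), np.array(carrier, dtype=np.int64)


def singleton_nn_summary(diploids: pd.DataFrame,
                         threshold: float = 100.0) -> dict:
    """Nearest-neighbour distance summary over per-diploid singleton sets.

    Distances are computed within each diploid (and, if a ``chrom`` column
    is present, within chromosomes).  Returns the number of singletons
    with a defined distance, the count below ``threshold`` and the
    percentage.
    """
    n_total = 0
    n_below = 0
    keys = ["diploid_id"] + (["chrom"] if "chrom" in diploids else [])
    for _, sub in diploids.groupby(keys, sort=False):
        p = np.sort(sub["pos"].to_numpy(dtype=float))
        if len(p) < 2:
            continue
        gaps = np.diff(p)
        nn = np.minimum(np.r_[gaps, np.inf], np.r_[np.inf, gaps])
        n_total += len(p)
        n_below += int((nn < threshold).sum())
    return {
        "n_singletons": n_total,
        "n_below": n_below,
        "percent_below": 100.0 * n_below / n_total if n_total else np.nan,
    }


@dataclass
class GenotypeConfig:
    n_sites: int = 500
    #: group name -> number of individuals
    groups: dict = field(default_factory=lambda: {"A": 20, "B": 20})
    #: SFS shape: P(allele count = i) ~ 1/i over 1..max_count
    max_count: int = 30
    #: fraction of sites with carriers drawn from a single group
    within_group_fraction: float = 0.0
    #: append an exact copy of the first individual
    duplicate_individual: bool = False


def simulate_genotype_matrix(config: GenotypeConfig | None = None,
                             seed: int | None = None):
    """Genotype carriage matrix with a configurable allele-count spectrum.

    Each site draws an allele count from the neutral-like 1/i spectrum,
    then places carriers either uniformly over all individuals or (for a
    ``within_group_fraction`` of sites) inside one random group, planting
    excess within-group rare-variant sharing.  Returns a
    :class:`~varscape.variant_io.VariantTable` via ``table_from_arrays``;
    use :func:`write_vcf` to serialize it.
    """
    from .variant_io import table_from_arrays

    config = config or GenotypeConfig()
    if any(n < 1 for n in config.groups.values()):
        raise ValueError("every group needs at least one individual")
    rng = np.random.default_rng(seed)
    samples, group_of = [], []
    for g, n in config.groups.items():
        samples += [f"{g}{i:04d}" for i in range(n)]
        group_of += [g] * n
    n_ind = len(samples)
    counts = np.arange(1, config.max_count + 1)
    probs = (1.0 / counts) / (1.0 / counts).sum()

    carr = np.zeros((config.n_sites, n_ind), dtype=np.int8)
    group_idx = {g: np.where(np.array(group_of) == g)[0]
                 for g in config.groups}
    group_names = list(config.groups)
    for s in range(config.n_sites):
        k = int(rng.choice(counts, p=probs))
        if rng.random() < config.within_group_fraction:
            pool = group_idx[group_names[rng.integers(len(group_names))]]
        else:
            pool = np.arange(n_ind)
        k = min(k, len(pool))
        carriers = rng.choice(pool, size=k, replace=False)
        carr[s, carriers] = 1

    if config.duplicate_individual:
        samples = samples + [samples[0] + "_dup"]
        carr = np.hstack([carr, carr[:, :1]])
        group_of = group_of + [group_of[0]]

    pos = np.sort(rng.choice(np.arange(1, config.n_sites * 100),
                             size=config.n_sites, replace=False))
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, config.n_sites)]
    alt = np.array([bases[(list(bases).index(r) + rng.integers(1, 4)) % 4]
                    for r in ref])
    table = table_from_arrays("chr1", pos, ref, alt, carr, samples)
    metadata = pd.DataFrame({
        "individual_id": samples,
        "study": ["S_" + g for g in group_of],
        "population_group": group_of,
    })
    return table, metadata


def write_vcf(table, path) -> None:
    """Serialize a VariantTable as a minimal sorted VCF v4.2 text file."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(table.variants["chrom"])
        for chrom in chroms:
            sub = table.variants[table.variants["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i, row in table.variants.iterrows():
            gts = "\t".join(gt_of[int(g)] for g in table.carriage[i])
            fh.write(f"{row['chrom']}\t{row['pos'] + 1}\t.\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


@dataclass
class DepletionConfig:
    n_genes: int = 4000
    cds_log_mean: float = math.log(1500.0)
    cds_log_sd: float = 0.75
    plof_rate_per_bp: float = 2e-3
    singleton_probability: float = 0.5
    #: set name -> (n_genes_in_set, rate multiplier)
    planted_sets: dict = field(default_factory=dict)


def simulate_depletion_inputs(config: DepletionConfig | None = None,
                              seed: int | None = None):
    """Gene table with L and S drawn from a length-dependent null.

    CDS lengths are log-normal; pLOF counts are Poisson with a per-bp rate
    (multiplied for genes in planted sets); singleton status of each pLOF
    variant is Bernoulli.  Returns (gene table with columns gene_id,
    cds_length, n_plof, L, S, plus one boolean column per planted set).
    """
    config = config or DepletionConfig()
    rng = np.random.default_rng(seed)
    n = config.n_genes
    cds = np.maximum(
        np.exp(rng.normal(config.cds_log_mean, config.cds_log_sd, n)), 50
    ).astype(np.int64)
    rate = np.full(n, config.plof_rate_per_bp)
    sets = {}
    for name, (size, mult) in config.planted_sets.items():
        members = rng.choice(n, size=size, replace=False)
        flag = np.zeros(n, dtype=bool)
        flag[members] = True
        sets[name] = flag
        rate[members] *= mult
    n_plof = rng.poisson(rate * cds)
    n_sing = rng.binomial(n_plof, config.singleton_probability)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(n_plof > 0, n_sing / np.maximum(n_plof, 1), np.nan)
    genes = pd.DataFrame({
        "gene_id": [f"G{i:05d}" for i in range(n)],
        "cds_length": cds, "n_plof": n_plof,
        "L": n_plof / cds, "S": S,
    })
    for name, flag in sets.items():
        genes[name] = flag
    return genes


@dataclass
class WindowFeatureConfig:
    n_windows: int = 2000
    n_features: int = 12
    beta0: float = 3.0
    #: non-intercept coefficients; padded with zeros to n_features
    beta: tuple = (0.5,)
    dispersion: float = 0.5  # NB size; counts ~ NB(mu, size)


def simulate_window_features(config: WindowFeatureConfig | None = None,
                             seed: int | None = None) -> pd.DataFrame:
    """Windowed NB counts from log mu = beta0 + X beta, features N(0, 1)."""
    config = config or WindowFeatureConfig()
    beta = np.zeros(config.n_features)
    beta[:len(config.beta)] = config.beta
    if not np.all(np.isfinite(beta)) or not np.isfinite(config.beta0):
        raise ValueError("coefficients must be finite")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(config.n_windows, config.n_features))
    mu = np.exp(config.beta0 + X @ beta)
    size = config.dispersion
    # NB as gamma-Poisson mixture: variance mu + mu^2/size
    lam = rng.gamma(shape=size, scale=mu / size)
    y = rng.poisson(lam)
    df = pd.DataFrame(X, columns=[f"X{m + 1}" for m in range(config.n_features)])
    df.insert(0, "count", y)
    df.insert(0, "component", 1)
    df.insert(0, "group", "sim")
    return df
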