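"""Two-transect clinal exome simulator with known ground truth.

Emulates the sampling design of a parallel latitudinal study: two transects
(western and eastern North America), five populations per transect spanning
a mean-annual-temperature gradient, ten diploid mice per population,
exome-like genes carrying a handful of SNPs each.

Population allele frequencies follow the Balding–Nichols model: each
transect clade has its own independent ancestral frequency
``p_bar ~ Uniform(0.05, 0.95)`` per site (shared clinal loci share one
``p_bar`` across transects), and each population draws a frequency
Beta-distributed around its clade's ``p_bar`` with parameter
``fst_target``.  Under this model the Hudson ratio-of-averages FST between
two populations of a clade equals ``fst_target`` in expectation — an
analytic oracle — while the independent ancestral draws separate the two
clades the way deep divergence between transects does.

Clinal selection is imposed at the gene level: every SNP of a clinal gene
has its population frequency shifted on the logit scale by
``cline_slope * z``, where ``z`` is the population's standardized
environmental value.  Shared clinal genes are clinal in both transects with
the same slope sign; the remainder are clinal in one transect only.

A polygenic body-weight phenotype (grams) is simulated with ``n_causal_snps``
additive loci, a fixed male–female offset, and residual noise scaled so the
genetic fraction of (genetic + residual) variance equals ``h2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variants_io import (
    MISSING,
    GenotypeMatrix,
    make_gene_annotation,
    write_bed,
    write_vcf,
)

_FREQ_EPS = 1e-4

#: default mean annual temperature (deg C) per population, south to north
DEFAULT_ENV = (20.0, 16.0, 11.0, 7.0, 3.0)
#: matching latitudes (degrees north) and per-transect longitudes
DEFAULT_LATITUDES = (32.2, 37.1, 40.2, 46.9, 53.5)
DEFAULT_LONGITUDES = {"west": -111.0, "east": -77.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic two-transect study.

    The defaults mirror the sampling design being emulated: 2 transects,
    5 populations each, 10 diploid samples per population, within-clade
    differentiation ``fst_target = 0.1``.
    """

    seed: int = 0
    n_transects: int = 2
    pops_per_transect: int = 5
    samples_per_pop: int = 10
    env_values: tuple[float, ...] = DEFAULT_ENV
    n_genes: int = 200
    snps_per_gene_mean: float = 5.0
    fst_target: float = 0.1
    clinal_fraction: float = 0.05
    shared_clinal_fraction: float = 0.5
    cline_slope: float = 1.5
    n_causal_snps: int = 10
    h2: float = 0.3
    sex_effect: float = 2.0
    missing_rate: float = 0.05
    residual_sd: float = 1.0
    genetic_sd: float = 1.5
    baseline_weight: float = 16.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must lie in (0, 1)")
        for name in ("clinal_fraction", "shared_clinal_fraction", "h2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if len(self.env_values) != self.pops_per_transect:
            raise ValueError("env_values must have one entry per population")
        diffs = np.diff(self.env_values)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("env_values must be strictly monotone")

    @property
    def transect_names(self) -> list[str]:
        return ["west", "east"][: self.n_transects] + [
            f"t{i}" for i in range(2, self.n_transects)
        ]


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analysis should recover."""

    clinal_sites: dict[str, np.ndarray]  # transect -> site indices
    clinal_genes: dict[str, list[str]]  # transect -> gene ids
    shared_clinal_genes: list[str]
    true_freqs: np.ndarray  # (n_pops, n_sites) post-cline frequencies
    causal_sites: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    causal_effects: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_json(self, path: str) -> None:
        obj = {
            "clinal_sites": {t: v.tolist() for t, v in self.clinal_sites.items()},
            "clinal_genes": self.clinal_genes,
            "shared_clinal_genes": self.shared_clinal_genes,
            "causal_sites": self.causal_sites.tolist(),
            "causal_effects": self.causal_effects.tolist(),
            "true_freqs": self.true_freqs.tolist(),
        }
        Path(path).write_text(json.dumps(obj))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _balding_nichols(rng, p_anc: np.ndarray, f: float) -> np.ndarray:
    scale = (1.0 - f) / f
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def _site_layout(config: SimConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene annotation and site table: genes 100 kb apart on 5 autosomes."""
    n_per_gene = 1 + rng.poisson(max(config.snps_per_gene_mean - 1.0, 0.0),
                                 size=config.n_genes)
    chroms, starts, ends, gids = [], [], [], []
    s_chrom, s_pos, s_gene = [], [], []
    n_chroms = 5
    per_chrom_count = np.zeros(n_chroms, dtype=int)
    for g in range(config.n_genes):
        c = g % n_chroms
        start = 100_000 + per_chrom_count[c] * 100_000
        per_chrom_count[c] += 1
        chrom = f"chr{c + 1}"
        gid = f"gene{g:04d}"
        chroms.append(chrom)
        starts.append(start)
        ends.append(start + 2_000)
        gids.append(gid)
        offsets = np.sort(rng.choice(2_000, size=n_per_gene[g], replace=False))
        for off in offsets:
            s_chrom.append(chrom)
            s_pos.append(start + int(off) + 1)  # 1-based VCF position
            s_gene.append(gid)
    ann = make_gene_annotation(
        pd.DataFrame({"gene_id": gids, "chrom": chroms, "start": starts, "end": ends})
    )
    sites = pd.DataFrame({"chrom": s_chrom, "pos": s_pos, "gene_id": s_gene})
    sites = sites.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return ann, sites


def simulate_allele_frequencies(
    config: SimConfig,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame, GroundTruth]:
    """Draw per-population, per-site allele frequencies.

    Returns
    -------
    pops : DataFrame
        population, transect, env (MAT), latitude, longitude per population.
    freqs : ndarray
        (n_pops, n_sites) true allele frequencies, clamped to
        ``[1e-4, 1 - 1e-4]``.
    sites : DataFrame
        chrom, pos (1-based), gene_id per site; the annotation is attached
        as ``sites.attrs['annotation']``.
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    ann, sites = _site_layout(config, rng)
    n_sites = len(sites)

    # population metadata
    rows = []
    for t, tname in enumerate(config.transect_names):
        lon = DEFAULT_LONGITUDES.get(tname, -90.0 + 10.0 * t)
        for k in range(config.pops_per_transect):
            rows.append(
                {
                    "population": f"{tname[0].upper()}{k + 1}",
                    "transect": tname,
                    "env": config.env_values[k],
                    "latitude": DEFAULT_LATITUDES[k % len(DEFAULT_LATITUDES)],
                    "longitude": lon + 0.5 * k,
                }
            )
    pops = pd.DataFrame(rows)

    # clinal gene assignment (gene-level: all SNPs of a clinal gene shift)
    gene_ids = ann["gene_id"].tolist()
    n_clinal = int(round(config.clinal_fraction * config.n_genes))
    clinal_gene_idx = rng.choice(config.n_genes, size=n_clinal, replace=False)
    n_shared = int(round(config.shared_clinal_fraction * n_clinal))
    shared = [gene_ids[i] for i in clinal_gene_idx[:n_shared]]
    rest = [gene_ids[i] for i in clinal_gene_idx[n_shared:]]
    clinal_genes = {t: list(shared) for t in config.transect_names}
    for i, g in enumerate(rest):
        t = config.transect_names[i % config.n_transects]
        clinal_genes[t].append(g)

    site_gene = sites["gene_id"].to_numpy()
    clinal_sites = {
        t: np.flatnonzero(np.isin(site_gene, clinal_genes[t]))
        for t in config.transect_names
    }

    # per-transect independent ancestral frequencies; shared clinal loci
    # reuse the first transect's draw so their cline is comparable
    shared_sites = np.flatnonzero(np.isin(site_gene, shared))
    p_bar_first = rng.uniform(0.05, 0.95, size=n_sites)
    env = np.asarray(config.env_values, dtype=float)
    z_env = (env - env.mean()) / env.std()
    freqs = np.empty((len(pops), n_sites))
    for t, tname in enumerate(config.transect_names):
        if t == 0:
            p_bar = p_bar_first
        else:
            p_bar = rng.uniform(0.05, 0.95, size=n_sites)
            p_bar[shared_sites] = p_bar_first[shared_sites]
        for k in range(config.pops_per_transect):
            row = t * config.pops_per_transect + k
            p = _balding_nichols(rng, p_bar, config.fst_target)
            cs = clinal_sites[tname]
            if config.cline_slope != 0.0 and len(cs):
                p = p.copy()
                p[cs] = _expit(
                    _logit(np.clip(p[cs], _FREQ_EPS, 1 - _FREQ_EPS))
                    + config.cline_slope * z_env[k]
                )
            freqs[row] = np.clip(p, _FREQ_EPS, 1.0 - _FREQ_EPS)

    sites.attrs["annotation"] = ann
    truth = GroundTruth(
        clinal_sites=clinal_sites,
        clinal_genes={t: sorted(v) for t, v in clinal_genes.items()},
        shared_clinal_genes=sorted(shared),
        true_freqs=freqs,
    )
    return pops, freqs, sites, truth


def simulate_genotypes(
    pops: pd.DataFrame,
    freqs: np.ndarray,
    sites: pd.DataFrame,
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw diploid calls ``Binomial(2, p)`` and apply MCAR missingness.

    Sex alternates male/female within each population; the sample table
    carries population, transect, coordinates, and sex.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_sites = len(sites)
    sample_rows = []
    calls = np.empty((len(pops) * config.samples_per_pop, n_sites), dtype=np.int8)
    r = 0
    for _, pop in pops.iterrows():
        p = freqs[pops.index.get_loc(pop.name)]
        for k in range(config.samples_per_pop):
            calls[r] = rng.binomial(2, p).astype(np.int8)
            sample_rows.append(
                {
                    "id": f"{pop['population']}_{k:02d}",
                    "population": pop["population"],
                    "transect": pop["transect"],
                    "latitude": pop["latitude"],
                    "longitude": pop["longitude"],
                    "sex": "M" if k % 2 == 0 else "F",
                }
            )
            r += 1
    if config.missing_rate > 0:
        drop = rng.random(calls.shape) < config.missing_rate
        calls[drop] = MISSING
    samples = pd.DataFrame(sample_rows)
    gm = GenotypeMatrix(
        sample_ids=samples["id"].tolist(),
        sites=sites.assign(ref="A", alt="G")[["chrom", "pos", "ref", "alt"]],
        calls=calls,
    )
    gm.sites["gene_id"] = sites["gene_id"].to_numpy()
    return gm, samples


def simulate_phenotype(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    config: SimConfig,
    truth: GroundTruth | None = None,
) -> np.ndarray:
    """Simulate body weight (grams) with additive SNP effects and a sex term.

    ``y = baseline + sum_j beta_j x_j + sex_effect * I(male) + eps``; the
    residual SD is chosen so genetic variance / (genetic + residual)
    variance equals ``h2``.  With ``h2 = 0`` all effects are zero and the
    residual SD is ``residual_sd``.  Missing causal genotypes are imputed at
    the population mean for simulation only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = gm.n_samples
    male = (samples["sex"].to_numpy() == "M").astype(float)

    if config.h2 > 0 and config.n_causal_snps == 0:
        raise ValueError("h2 > 0 requires at least one causal SNP")
    if config.n_causal_snps > gm.n_sites:
        raise ValueError("n_causal_snps exceeds the number of sites")

    causal = rng.choice(gm.n_sites, size=config.n_causal_snps, replace=False)
    causal.sort()
    if config.h2 == 0.0:
        effects = np.zeros(len(causal))
        g = np.zeros(n)
        sigma = config.residual_sd
    else:
        effects = rng.normal(0.0, 1.0, size=len(causal))
        x = gm.calls[:, causal].astype(float)
        x[x == MISSING] = np.nan
        pops_arr = samples["population"].to_numpy()
        for pop in pd.unique(pops_arr):
            rows = pops_arr == pop
            m = np.nanmean(x[rows], axis=0)
            block = x[rows]
            ii, jj = np.where(np.isnan(block))
            block[ii, jj] = np.nan_to_num(m)[jj]
            x[rows] = block
        g = x @ effects
        if g.var() == 0:
            raise ValueError("causal genotypes are constant; cannot reach h2 > 0")
        # rescale to a realistic genetic SD in grams; h2 sets the residual
        scale = config.genetic_sd / g.std()
        effects = effects * scale
        g = g * scale
        if config.h2 == 1.0:
            sigma = 0.0
        else:
            sigma = np.sqrt(g.var() * (1.0 - config.h2) / config.h2)
    y = (
        config.baseline_weight
        + g
        + config.sex_effect * male
        + rng.normal(0.0, sigma, size=n)
    )
    if truth is not None:
        truth.causal_sites = causal
        truth.causal_effects = effects
    return y


@dataclass
class SimulatedDataset:
    """Bundle of all simulator outputs for one configuration."""

    config: SimConfig
    gm: GenotypeMatrix
    samples: pd.DataFrame
    pops: pd.DataFrame
    annotation: pd.DataFrame
    truth: GroundTruth


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: frequencies, genotypes, phenotype."""
    pops, freqs, sites, truth = simulate_allele_frequencies(config)
    gm, samples = simulate_genotypes(pops, freqs, sites, config)
    y = simulate_phenotype(gm, samples, config, truth)
    samples["body_weight_g"] = y
    return SimulatedDataset(
        config=config,
        gm=gm,
        samples=samples,
        pops=pops,
        annotation=sites.attrs["annotation"],
        truth=truth,
    )


def write_fixture(ds: SimulatedDataset, outdir: str) -> dict[str, str]:
    """Write VCF, sample TSV, environment TSV, gene BED, and truth JSON.

    Re-reading the files reproduces the in-memory objects exactly; with a
    fixed seed the files are byte-identical across runs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(out / "genotypes.vcf"),
        "samples": str(out / "samples.tsv"),
        "env": str(out / "environment.tsv"),
        "bed": str(out / "genes.bed"),
        "truth": str(out / "ground_truth.json"),
    }
    write_vcf(ds.gm, paths["vcf"])
    ds.samples.to_csv(paths["samples"], sep="\t", index=False, float_format="%.6f")
    ds.pops.rename(columns={"env": "mat_c"})[["population", "mat_c"]].to_csv(
        paths["env"], sep="\t", index=False
    )
    write_bed(ds.annotation, paths["bed"])
    ds.truth.to_json(paths["truth"])
    return paths
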