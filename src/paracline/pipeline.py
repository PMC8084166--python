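"""Config-driven end-to-end orchestration.

Stages: acquire data (simulate or ingest) -> site filters -> population
summaries and tree -> per-transect environmental scan -> mixed-model GWAS
-> between-transect gene-overlap test.  All randomness derives from one
configured seed, fanned out to per-stage child seeds so stages are
reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envassoc as ea
from . import gwas as gw
from . import parallelism as pl
from . import popgen as pg
from . import synthetic_data as sd
from . import variants_io as vio

logger = logging.getLogger("paracline")

__version__ = "0.1.0"

_FILTER_DEFAULTS = {"maf_min": 0.05, "callrate": 0.8,
                    "ld_window_bp": 50_000, "ld_r2": 0.5}
_ENV_DEFAULTS = {"k": 2, "q_loose": 0.05, "q_strict": 0.001,
                 "min_snps_strict": 2, "lambda_override": None}
_GWAS_DEFAULTS = {"fdr": 0.05, "reml": True, "transect": None}
_PERM_DEFAULTS = {"n_perm": 100_000, "universe_size": None}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    simulate: dict | None = None
    inputs: dict | None = None
    filters: dict = field(default_factory=dict)
    envassoc: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=dict)
    parallelism: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must name exactly one of 'simulate' or 'inputs'")
        self.filters = {**_FILTER_DEFAULTS, **self.filters}
        self.envassoc = {**_ENV_DEFAULTS, **self.envassoc}
        self.gwas = {**_GWAS_DEFAULTS, **self.gwas}
        self.parallelism = {**_PERM_DEFAULTS, **self.parallelism}
        for name, block, allowed in (
            ("filters", self.filters, _FILTER_DEFAULTS),
            ("envassoc", self.envassoc, _ENV_DEFAULTS),
            ("gwas", self.gwas, _GWAS_DEFAULTS),
            ("parallelism", self.parallelism, _PERM_DEFAULTS),
        ):
            unknown = set(block) - set(allowed)
            if unknown:
                raise ValueError(f"unknown keys in {name!r}: {sorted(unknown)}")
        if self.inputs is not None:
            required = {"vcf", "samples", "env", "bed"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing keys: {sorted(missing)}")
            for key in required:
                p = Path(self.inputs[key])
                if not p.exists():
                    raise ValueError(f"input file does not exist: {p}")


_TOP_KEYS = {"seed", "output_dir", "simulate", "inputs",
             "filters", "envassoc", "gwas", "parallelism"}


def validate_config(path: str) -> PipelineConfig:
    """Parse, default, and schema-check a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("seed", "output_dir"):
        if key not in raw:
            raise ValueError(f"config missing required key {key!r}")
    if raw.get("simulate") is not None:
        valid_sim = {f.name for f in sd.SimConfig.__dataclass_fields__.values()}
        bad = set(raw["simulate"]) - valid_sim
        if bad:
            raise ValueError(f"unknown keys in 'simulate': {sorted(bad)}")
    return PipelineConfig(**raw)


def _child_seed(root_seed: int, stage: int) -> int:
    return int(
        np.random.SeedSequence([root_seed, stage]).generate_state(1)[0] % (2**31)
    )


@dataclass
class RunReport:
    config_seed: int
    version: str
    counts: dict = field(default_factory=dict)
    wall_time_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    overlap: dict | None = None

    def to_json(self, path: str) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.output_dir)
    for sub in ("vcf", "tables", "trees"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    report = RunReport(config_seed=config.seed, version=__version__)
    t_all = time.time()

    # ---- stage 1: data -------------------------------------------------
    t0 = time.time()
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", _child_seed(config.seed, 0))
        ds = sd.simulate_dataset(sd.SimConfig(**sim_kwargs))
        gm, samples, ann = ds.gm, ds.samples, ds.annotation
        env_table = ds.pops.rename(columns={"env": "mat_c"})[["population", "mat_c"]]
        sd.write_fixture(ds, out / "vcf")
    else:
        gm = vio.read_vcf(config.inputs["vcf"])
        samples = vio.read_sample_table(config.inputs["samples"])
        env_table = vio.read_env_table(config.inputs["env"])
        ann = vio.read_bed(config.inputs["bed"])
    report.counts["sites_raw"] = gm.n_sites
    report.counts["samples"] = gm.n_samples
    report.wall_time_s["data"] = round(time.time() - t0, 3)
    logger.info("data stage: %d samples x %d sites", gm.n_samples, gm.n_sites)

    # ---- stage 2: filters ----------------------------------------------
    t0 = time.time()
    gm = vio.drop_sex_chromosomes(gm)
    report.counts["sites_autosomal"] = gm.n_sites
    gm = vio.filter_sites(
        gm,
        samples,
        maf_min=config.filters["maf_min"],
        per_pop_callrate=config.filters["callrate"],
    )
    report.counts["sites_filtered"] = gm.n_sites
    report.wall_time_s["filters"] = round(time.time() - t0, 3)
    logger.info("filter stage: %d sites retained", gm.n_sites)

    # ---- stage 3: population summaries ---------------------------------
    t0 = time.time()
    div = pg.diversity_table(gm, samples, n_callable_sites=gm.n_sites)
    div.to_csv(out / "tables" / "diversity.tsv", sep="\t", index=False)
    fst = pg.fst_matrix(gm, samples)
    fst.to_csv(out / "tables" / "fst.tsv", sep="\t")
    scores, frac = pg.genetic_pca(gm, n_components=5)
    pca = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
    pca.insert(0, "id", gm.sample_ids)
    pca.to_csv(out / "tables" / "pca_scores.tsv", sep="\t", index=False)
    coords = samples.groupby("population", sort=False)[
        ["latitude", "longitude"]
    ].first().reset_index()
    ibd: dict[str, float] = {}
    for transect in pd.unique(samples["transect"]):
        pops_t = samples.loc[samples["transect"] == transect, "population"].unique()
        sub_fst = fst.loc[pops_t, pops_t]
        try:
            slope, intercept, r2 = pg.ibd_regression(
                sub_fst, coords[coords["population"].isin(pops_t)]
            )
            ibd[transect] = r2
        except ValueError:
            pass
    pruned = vio.ld_prune(
        gm,
        window_bp=config.filters["ld_window_bp"],
        r2_max=config.filters["ld_r2"],
    )
    report.counts["sites_ld_pruned"] = pruned.n_sites
    tree = pg.bootstrap_support(pruned, n_boot=100, seed=_child_seed(config.seed, 3))
    pg.write_newick(tree, out / "trees" / "nj_bootstrap.nwk")
    report.counts["ibd_r2"] = ibd
    report.wall_time_s["popgen"] = round(time.time() - t0, 3)
    logger.info("popgen stage done (LD-pruned sites: %d)", pruned.n_sites)

    # ---- stage 4: per-transect environmental scan -----------------------
    t0 = time.time()
    env_by_pop = env_table.set_index("population")["mat_c"]
    outlier_sets: dict[str, ea.OutlierGeneSet] = {}
    strict_sets: dict[str, ea.OutlierGeneSet] = {}
    transects = list(pd.unique(samples["transect"]))
    for transect in transects:
        rows = np.flatnonzero((samples["transect"] == transect).to_numpy())
        gm_t = gm.take_samples(rows)
        freqs = gm_t.allele_frequencies()
        poly = (freqs > 0) & (freqs < 1)
        gm_t = gm_t.take_sites(poly)
        env = samples.iloc[rows]["population"].map(env_by_pop).to_numpy(dtype=float)
        res = ea.env_association(
            gm_t,
            env,
            K=config.envassoc["k"],
            lambda_override=config.envassoc["lambda_override"],
        )
        snp2gene = vio.assign_snps_to_genes(gm_t, ann)
        loose = ea.outlier_genes(res, snp2gene, config.envassoc["q_loose"], 1)
        strict = ea.outlier_genes(
            res, snp2gene, config.envassoc["q_strict"],
            config.envassoc["min_snps_strict"],
        )
        outlier_sets[transect] = loose
        strict_sets[transect] = strict
        res.to_frame().to_csv(
            out / "tables" / f"envassoc_{transect}.tsv", sep="\t", index=False
        )
        report.counts[f"outlier_snps_{transect}"] = int(
            (res.q < config.envassoc["q_loose"]).sum()
        )
        report.counts[f"outlier_genes_loose_{transect}"] = len(loose.genes)
        report.counts[f"outlier_genes_strict_{transect}"] = len(strict.genes)
        logger.info(
            "envassoc %s: lambda=%.3f, %d loose outlier genes",
            transect, res.lambda_gc, len(loose.genes),
        )
    report.wall_time_s["envassoc"] = round(time.time() - t0, 3)

    # ---- stage 5: GWAS ---------------------------------------------------
    t0 = time.time()
    gwas_transect = config.gwas["transect"] or transects[0]
    keep = (samples["transect"] == gwas_transect).to_numpy()
    if "exclude" in samples.columns:
        keep &= ~samples["exclude"].fillna(False).astype(bool).to_numpy()
    keep &= samples["body_weight_g"].notna().to_numpy()
    rows = np.flatnonzero(keep)
    gm_g = gm.take_samples(rows)
    freqs = gm_g.allele_frequencies()
    poly = (freqs > 0) & (freqs < 1)
    gm_g = gm_g.take_sites(poly)
    sub = samples.iloc[rows]
    y = sub["body_weight_g"].to_numpy(dtype=float)
    w = np.column_stack(
        [np.ones(len(rows)), (sub["sex"] == "M").to_numpy(dtype=float)]
    )
    kin = gw.centered_kinship(gm_g)
    assoc = gw.lmm_association(
        gm_g, y, w, kin, reml=config.gwas["reml"], fdr=config.gwas["fdr"]
    )
    assoc.to_csv(out / "tables" / "gwas.tsv", sep="\t", index=False)
    hits = assoc[assoc["q"] < config.gwas["fdr"]]
    snp2gene_g = vio.assign_snps_to_genes(gm_g, ann)
    gpve = gw.gene_pve(assoc, snp2gene_g)
    gpve.to_csv(out / "tables" / "gene_pve.tsv", sep="\t", index=False)
    report.counts["gwas_samples"] = len(rows)
    report.counts["gwas_hits"] = int(len(hits))
    report.wall_time_s["gwas"] = round(time.time() - t0, 3)
    logger.info("gwas stage (%s): %d hits", gwas_transect, len(hits))

    # ---- stage 6: parallelism -------------------------------------------
    t0 = time.time()
    if len(transects) >= 2:
        a, b = transects[0], transects[1]
        genes_a = outlier_sets[a].gene_ids()
        genes_b = outlier_sets[b].gene_ids()
        universe = config.parallelism["universe_size"] or len(ann)
        if genes_a and genes_b:
            obs = pl.observed_overlap(genes_a, genes_b, ann["gene_id"])
            test = pl.permutation_overlap_test(
                len(genes_a),
                len(genes_b),
                universe,
                observed=obs,
                n_perm=config.parallelism["n_perm"],
                seed=_child_seed(config.seed, 6),
            )
            test.to_json(str(out / "overlap.json"))
            report.overlap = json.loads(test.to_json())
            logger.info(
                "overlap: observed=%d expected=%.2f p=%.2g",
                obs, test.expected_perm, test.p_perm,
            )
        else:
            logger.info("overlap test skipped: an outlier set is empty")
    report.wall_time_s["parallelism"] = round(time.time() - t0, 3)
    report.wall_time_s["total"] = round(time.time() - t_all, 3)
    report.outputs = {"dir": str(out)}
    report.to_json(out / "report.json")
    return report


def summarize(report: RunReport) -> str:
    """Human-readable run summary."""
    lines = [f"paracline run (seed {report.config_seed})"]
    for key, val in report.counts.items():
        lines.append(f"  {key}: {val}")
    if report.overlap is not None:
        ov = report.overlap
        lines.append(
            "  overlap: observed={observed} expected={expected_perm:.2f} "
            "p_perm={p_perm:.3g}".format(**ov)
        )
    else:
        lines.append("  overlap test: skipped (empty outlier gene set)")
    return "\n".join(lines)


def _setup_logging(logfile: Path) -> None:
    logger.setLevel(logging.INFO)
    have = {type(h) for h in logger.handlers}
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if logging.StreamHandler not in have:
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    for h in [h for h in logger.handlers if isinstance(h, logging.FileHandler)]:
        logger.removeHandler(h)
        h.close()
    fh = logging.FileHandler(logfile)
    fh.setFormatter(fmt)
    logger.addHandler(fh)
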