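"""Genotype-matrix container, standard-format I/O, and site filters.

Genotypes are stored as an ``int8`` samples x sites matrix with values in
``{0, 1, 2}`` counting copies of the alternate allele, and ``-1`` for a
missing call.  Positions are 1-based in the site table (VCF convention) and
converted to 0-based half-open coordinates for interval work (BED
convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("paracline")

MISSING = -1

#: chromosome names treated as sex chromosomes and excluded from scans
SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})

SAMPLE_COLUMNS = ("id", "population", "transect", "latitude", "longitude", "sex")


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotype calls for a set of samples.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample identifiers (VCF column order).
    sites : pandas.DataFrame
        One row per site with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``; positions strictly increasing within a chromosome.
    calls : numpy.ndarray
        ``int8`` array of shape ``(n_samples, n_sites)`` with values in
        ``{0, 1, 2, -1}``.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        if len(self.sites):
            if (self.sites["ref"] == self.sites["alt"]).any():
                raise ValueError("ref allele equals alt allele at some site")
            for _, grp in self.sites.groupby("chrom", sort=False):
                if not grp["pos"].is_monotonic_increasing:
                    raise ValueError("positions not sorted within chromosome")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_ids(self) -> pd.Series:
        return self.sites["chrom"].astype(str) + ":" + self.sites["pos"].astype(str)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per site from non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n_chrom = 2.0 * obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chrom > 0, alt / n_chrom, np.nan)

    def imputed(self) -> np.ndarray:
        """Float copy of the calls with missing entries set to the site mean."""
        x = self.calls.astype(float)
        x[x == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(x, axis=0)
        col_mean = np.nan_to_num(col_mean)
        idx = np.where(np.isnan(x))
        x[idx] = col_mean[idx[1]]
        return x

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            sites=self.sites.copy(),
            calls=self.calls[index, :].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.sites[["chrom", "pos", "ref", "alt"]].equals(
                other.sites[["chrom", "pos", "ref", "alt"]]
            )
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

# cyvcf2 gt_types codes: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
_GT_DECODE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; multi-allelic sites and indels are
    skipped (the count is logged).  ``./.`` becomes missing; phasing is
    ignored.
    """
    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    rows, chroms, poss, refs, alts = [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        rows.append(_GT_DECODE[var.gt_types])
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    sites = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "pos": pd.Series(poss, dtype=int),
            "ref": pd.Series(refs, dtype=str),
            "alt": pd.Series(alts, dtype=str),
        }
    )
    calls = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids=sample_ids, sites=sites, calls=calls)


_GT_ENCODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=paracline\n")
        for chrom, grp in gm.sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        sites = gm.sites
        for j in range(gm.n_sites):
            gts = "\t".join(_GT_ENCODE[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{sites.chrom.iloc[j]}\t{sites.pos.iloc[j]}\t.\t"
                f"{sites.ref.iloc[j]}\t{sites.alt.iloc[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def read_sample_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if df["population"].isna().any() or (df["population"].astype(str) == "").any():
        raise ValueError("sample table has empty population entries")
    return df


def read_env_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("population", "mat_c"):
        if col not in df.columns:
            raise ValueError(f"environment table missing column {col!r}")
    return df


def read_bed(path: str) -> pd.DataFrame:
    """Read a 4+ column BED of gene intervals (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "start": int, "end": int, "gene_id": str},
    )
    return make_gene_annotation(df)


def make_gene_annotation(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "gene_name" not in df.columns:
        df["gene_name"] = df["gene_id"]
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene annotation has start >= end")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    return df[["gene_id", "gene_name", "chrom", "start", "end"]].reset_index(drop=True)


def write_bed(ann: pd.DataFrame, path: str) -> None:
    ann[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def drop_sex_chromosomes(gm: GenotypeMatrix) -> GenotypeMatrix:
    keep = ~gm.sites["chrom"].isin(SEX_CHROMS).to_numpy()
    return gm.take_sites(keep)


def filter_sites(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    maf_min: float = 0.05,
    per_pop_callrate: float = 0.8,
    per_pop_maf: bool = False,
) -> GenotypeMatrix:
    """Apply the study-style site filters.

    A site is kept when its minor-allele frequency (from non-missing calls)
    is at least ``maf_min`` — globally by default, within every population
    when ``per_pop_maf`` — AND the fraction of non-missing calls is at least
    ``per_pop_callrate`` within **every** population.  Site order is
    preserved; the filter is idempotent.
    """
    if samples["id"].tolist() != gm.sample_ids:
        samples = samples.set_index("id").loc[gm.sample_ids].reset_index()
    pops = samples["population"].to_numpy()
    obs = gm.calls != MISSING
    keep = np.ones(gm.n_sites, dtype=bool)
    for pop in pd.unique(pops):
        rows = pops == pop
        if rows.sum() == 0:
            raise ValueError(f"population {pop!r} has zero samples")
        callrate = obs[rows].mean(axis=0)
        keep &= callrate >= per_pop_callrate
        if per_pop_maf:
            keep &= _maf(gm.calls[rows]) >= maf_min
    if not per_pop_maf:
        keep &= _maf(gm.calls) >= maf_min
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_sites: removed %d of %d sites", removed, gm.n_sites)
    return gm.take_sites(keep)


def _maf(calls: np.ndarray) -> np.ndarray:
    obs = calls != MISSING
    n_chrom = 2.0 * obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / n_chrom, np.nan)
    maf = np.minimum(p, 1.0 - p)
    return np.where(np.isnan(maf), -1.0, maf)


def ld_prune(
    gm: GenotypeMatrix, window_bp: int = 50_000, r2_max: float = 0.5
) -> GenotypeMatrix:
    """Greedy LD pruning in non-overlapping physical windows.

    Within each ``window_bp`` window (per chromosome, anchored at position
    0), SNPs are scanned left to right; a SNP is dropped when its squared
    Pearson correlation with any already-kept SNP in the window exceeds
    ``r2_max``.  Correlations use pairwise-complete observations.
    """
    keep = np.zeros(gm.n_sites, dtype=bool)
    chroms = gm.sites["chrom"].to_numpy()
    windows = gm.sites["pos"].to_numpy() // window_bp
    x = gm.calls.astype(float)
    x[gm.calls == MISSING] = np.nan
    for chrom in pd.unique(chroms):
        on_chrom = chroms == chrom
        for win in pd.unique(windows[on_chrom]):
            idx = np.flatnonzero(on_chrom & (windows == win))
            kept: list[int] = []
            for j in idx:
                if all(_r2(x[:, j], x[:, k]) <= r2_max for k in kept):
                    kept.append(int(j))
            keep[kept] = True
    return gm.take_sites(keep)


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    both = ~(np.isnan(a) | np.isnan(b))
    if both.sum() < 2:
        return 0.0
    aa, bb = a[both], b[both]
    if aa.std() == 0 or bb.std() == 0:
        return 0.0
    r = np.corrcoef(aa, bb)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# SNP-to-gene assignment
# ---------------------------------------------------------------------------


def assign_snps_to_genes(gm: GenotypeMatrix, ann: pd.DataFrame) -> dict[int, list[str]]:
    """Map each site index to the genes whose interval contains it.

    VCF positions (1-based) are converted to 0-based before testing against
    the BED-style half-open intervals.  A SNP in overlapping genes maps to
    all of them; a SNP in no gene is absent from the result.
    """
    out: dict[int, list[str]] = {}
    pos0 = gm.sites["pos"].to_numpy() - 1
    chroms = gm.sites["chrom"].to_numpy()
    for chrom, genes in ann.groupby("chrom", sort=False):
        site_idx = np.flatnonzero(chroms == chrom)
        if len(site_idx) == 0:
            continue
        p = pos0[site_idx]
        for _, g in genes.iterrows():
            hit = site_idx[(p >= g["start"]) & (p < g["end"])]
            for j in hit:
                out.setdefault(int(j), []).append(g["gene_id"])
    return out


def genes_of_sites(snp_to_genes: dict[int, list[str]], site_index) -> set[str]:
    """Union of genes hit by the given site indices."""
    genes: set[str] = set()
    for j in site_index:
        genes.update(snp_to_genes.get(int(j), ()))
    return genes
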