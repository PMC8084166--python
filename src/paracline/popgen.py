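"""Population-genomic summaries and distance-based phylogenetics.

Implements within-population diversity (pi and Watterson's theta per
callable site), Hudson's ratio-of-averages pairwise FST, genotype PCA,
isolation-by-distance regression of FST on great-circle distance,
allele-sharing distances, Saitou–Nei neighbor joining with deterministic
tie-breaking, site-bootstrap branch support, and Newick output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variants_io import MISSING, GenotypeMatrix

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    population: str
    pi_per_site: float
    theta_w_per_site: float
    n_segregating: int
    n_callable_sites: int


def nucleotide_diversity(
    gm: GenotypeMatrix,
    sample_index: np.ndarray,
    n_callable_sites: int,
    population: str = "",
) -> DiversitySummary:
    """Per-site pi and Watterson's theta for one population.

    Per segregating site, ``pi_s = (n/(n-1)) * 2 p (1-p)`` with ``n`` the
    non-missing allele count; ``theta_w = S / a_{n-1}`` using the modal
    allele count over counted sites.  Both are divided by the callable-site
    count supplied by the caller (segregating sites alone understate the
    denominator for exome data).
    """
    if n_callable_sites <= 0:
        raise ValueError("n_callable_sites must be positive")
    calls = gm.calls[np.asarray(sample_index)]
    obs = calls != MISSING
    n_chrom = 2 * obs.sum(axis=0)
    usable = n_chrom >= 2
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(usable, alt / np.maximum(n_chrom, 1), np.nan)
    seg = usable & (p > 0) & (p < 1)
    n_seg = int(seg.sum())
    if n_seg == 0:
        return DiversitySummary(population, 0.0, 0.0, 0, n_callable_sites)
    n_s = n_chrom[seg].astype(float)
    pi_sum = float(np.sum(n_s / (n_s - 1.0) * 2.0 * p[seg] * (1.0 - p[seg])))
    # modal chromosome count over counted (segregating) sites
    vals, counts = np.unique(n_chrom[seg], return_counts=True)
    n_mode = int(vals[np.argmax(counts)])
    a_n = float(np.sum(1.0 / np.arange(1, n_mode)))
    theta = n_seg / a_n / n_callable_sites
    return DiversitySummary(
        population, pi_sum / n_callable_sites, theta, n_seg, n_callable_sites
    )


def diversity_table(
    gm: GenotypeMatrix, samples: pd.DataFrame, n_callable_sites: int
) -> pd.DataFrame:
    pops = samples["population"].to_numpy()
    rows = []
    for pop in pd.unique(pops):
        s = nucleotide_diversity(
            gm, np.flatnonzero(pops == pop), n_callable_sites, pop
        )
        rows.append(vars(s))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------


def hudson_fst_components(
    gm: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[float, float]:
    """Summed Hudson numerator and denominator over usable sites.

    ``N_s = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)``,
    ``D_s = p1(1-p2) + p2(1-p1)``, with ``n`` in alleles; sites need at
    least 2 non-missing alleles in each population.
    """
    num = den = 0.0
    stats_ = []
    for idx in (idx_a, idx_b):
        calls = gm.calls[np.asarray(idx)]
        obs = calls != MISSING
        n = 2.0 * obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        stats_.append((n, alt))
    n1, a1 = stats_[0]
    n2, a2 = stats_[1]
    usable = (n1 >= 2) & (n2 >= 2)
    if not usable.any():
        raise ValueError("no sites with >=2 alleles in both populations")
    n1, a1, n2, a2 = n1[usable], a1[usable], n2[usable], a2[usable]
    p1, p2 = a1 / n1, a2 / n2
    num_s = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den_s = p1 * (1 - p2) + p2 * (1 - p1)
    num = float(num_s.sum())
    den = float(den_s.sum())
    return num, den


def pairwise_fst(gm: GenotypeMatrix, idx_a, idx_b) -> float:
    """Hudson FST as the ratio of summed numerators to summed denominators."""
    num, den = hudson_fst_components(gm, idx_a, idx_b)
    if den == 0:
        raise ValueError("zero FST denominator (no variation)")
    return num / den


def fst_matrix(gm: GenotypeMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Symmetric population-pair FST matrix (diagonal zero)."""
    pops_arr = samples["population"].to_numpy()
    pops = list(pd.unique(pops_arr))
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            f = pairwise_fst(
                gm, np.flatnonzero(pops_arr == a), np.flatnonzero(pops_arr == b)
            )
            out.loc[a, b] = out.loc[b, a] = f
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def genetic_pca(
    gm: GenotypeMatrix, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the mean-imputed, column-centered genotype matrix.

    Returns sample scores (n x k) and the fraction of variance per
    component.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = gm.imputed()
    x -= x.mean(axis=0)
    k = min(n_components, gm.n_samples - 1, gm.n_sites)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    scores = u[:, :k] * s[:k]
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, frac


# ---------------------------------------------------------------------------
# Isolation by distance
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    la1, lo1, la2, lo2 = map(math.radians, (lat1, lon1, lat2, lon2))
    a = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def ibd_regression(
    fst: pd.DataFrame, coords: pd.DataFrame, linearize: bool = False
) -> tuple[float, float, float]:
    """OLS of pairwise FST on great-circle distance (km).

    ``coords`` needs columns population/latitude/longitude.  With
    ``linearize`` the response is ``FST / (1 - FST)``.  Returns
    (slope, intercept, R^2).
    """
    coords = coords.set_index("population")
    pops = list(fst.index)
    d, f = [], []
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            d.append(
                haversine_km(
                    coords.loc[a, "latitude"],
                    coords.loc[a, "longitude"],
                    coords.loc[b, "latitude"],
                    coords.loc[b, "longitude"],
                )
            )
            v = fst.loc[a, b]
            f.append(v / (1 - v) if linearize else v)
    if len(d) < 3:
        raise ValueError("need at least 3 population pairs")
    if np.ptp(d) == 0:
        raise ValueError("all populations share identical coordinates")
    res = stats.linregress(d, f)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------


def distance_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Allele-sharing distance ``d = mean(|x_i - x_j| / 2)`` over shared sites."""
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = gm.calls.astype(float)
    x[gm.calls == MISSING] = np.nan
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :]) / 2.0
        cnt = np.sum(~np.isnan(diff), axis=1)
        if np.any(cnt == 0):
            raise ValueError("a sample pair shares no genotyped sites")
        row = np.nansum(diff, axis=1) / cnt
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return pd.DataFrame(d, index=gm.sample_ids, columns=gm.sample_ids)


@dataclass
class TreeNode:
    """Node of an unrooted tree (stored with an arbitrary trifurcating root)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]


@dataclass
class Tree:
    root: TreeNode
    negative_branches_clamped: bool = False

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, canonicalized over the leaf set."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset] = set()
        def visit(node):
            for c in node.children:
                side = frozenset(c.leaf_names())
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(_canon(side, all_leaves))
                visit(c)
        visit(self.root)
        return out


def _canon(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def neighbor_joining(dist: pd.DataFrame) -> Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lowest (i, j) index pair in
    the current node ordering; negative branch lengths are clamped to 0 and
    flagged on the returned tree.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = list(dist.index)
    m = len(labels)
    if m < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=str(lbl)) for lbl in labels]
    d = d.copy()
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        # floating-point rounding makes q asymmetric; search the upper
        # triangle only, with the lowest-index pair breaking ties
        q[np.tril_indices(n)] = np.inf
        best = q.min()
        ii, jj = np.where(q == best)
        i, j = min(zip(ii, jj))
        li_raw = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj_raw = d[i, j] - li_raw
        nodes[i].length = clamp(li_raw)
        nodes[j].length = clamp(lj_raw)
        new = TreeNode(children=[nodes[i], nodes[j]])
        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], d_new[keep][None, :]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    # final three nodes join at the root with path-equation lengths
    a, b, c = 0, 1, 2
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    return Tree(root=TreeNode(children=nodes), negative_branches_clamped=clamped)


def tree_path_lengths(tree: Tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix (for additivity checks)."""
    # collect (leafset, cumulative length) via postorder
    names = tree.leaf_names()
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    dist = np.zeros((n, n))

    def visit(node) -> list[tuple[int, float]]:
        if node.is_leaf:
            return [(idx[node.name], node.length)]
        below: list[list[tuple[int, float]]] = [visit(c) for c in node.children]
        for gi in range(len(below)):
            for gj in range(gi + 1, len(below)):
                for li, di in below[gi]:
                    for lj, dj in below[gj]:
                        dist[li, lj] = dist[lj, li] = di + dj
        merged = [(li, di + node.length) for grp in below for li, di in grp]
        return merged

    visit(tree.root)
    return pd.DataFrame(dist, index=names, columns=names)


def bootstrap_support(
    gm: GenotypeMatrix, n_boot: int = 100, seed: int = 0
) -> Tree:
    """NJ tree with site-bootstrap support on internal edges.

    Sites are resampled with replacement ``n_boot`` times; support for each
    internal bipartition of the full-data tree is the percentage of
    replicate trees containing it.
    """
    if gm.n_samples < 4:
        raise ValueError("bootstrap support needs at least 4 taxa")
    tree = neighbor_joining(distance_matrix(gm))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        # sorted so the resampled site table keeps positions non-decreasing;
        # the distance matrix only depends on the resampled multiset
        take = np.sort(rng.integers(0, gm.n_sites, size=gm.n_sites))
        rep = neighbor_joining(distance_matrix(gm.take_sites(take)))
        rep_bp = rep.bipartitions()
        for bp in target:
            if bp in rep_bp:
                counts[bp] += 1
    universe = frozenset(tree.leaf_names())

    def annotate(node):
        for c in node.children:
            if not c.is_leaf:
                side = _canon(frozenset(c.leaf_names()), universe)
                if side in counts:
                    c.support = 100.0 * counts[side] / n_boot
            annotate(c)

    annotate(tree.root)
    return tree


def to_newick(tree: Tree) -> str:
    def fmt(node) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.10g}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:g}"
        return f"({inner}){label}:{node.length:.10g}"
    inner = ",".join(fmt(c) for c in tree.root.children)
    return f"({inner});"


def write_newick(tree: Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
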