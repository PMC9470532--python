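"""VAF-distribution deconvolution and clonality classification.

A sample's variant allele fraction (VAF) distribution is smoothed by a
Gaussian kernel density estimate on [0, 1] (with boundary reflection),
local maxima define subclonal clusters, cluster membership is the set of
mutations between the flanking local minima, and clusters holding less
than 10% of mutations are dropped.  Under the diploid heterozygous model a
cluster at mean VAF v corresponds to a subclone occupying min(1, 2v) of
the cell population; a dominant non-tail cluster near VAF 0.5 marks a
clonal sample, lower dominant clusters mark oligoclonal ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VAFClusterSet",
    "estimate_density",
    "find_clusters",
    "subclone_fraction",
    "classify_clonality",
    "silverman_bandwidth",
]

GRID_STEP = 0.002
MIN_MUTATIONS = 10


@dataclass
class VAFCluster:
    mean_vaf: float
    mutation_fraction: float
    subclone_fraction: float
    n_mutations: int
    bounds: tuple[float, float]


@dataclass
class VAFClusterSet:
    """KDE-derived VAF clusters of one sample, ordered by mean VAF."""

    clusters: list[VAFCluster]
    bandwidth: float
    n_mutations: int
    classification: str | None = None
    grid: np.ndarray = field(default=None, repr=False)
    density: np.ndarray = field(default=None, repr=False)


def silverman_bandwidth(vafs: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, floored for degenerate input."""
    vafs = np.asarray(vafs, dtype=float)
    n = vafs.size
    sd = vafs.std(ddof=1)
    iqr = np.subtract(*np.percentile(vafs, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-1 / 5)
    return max(float(h), 1e-3)


def estimate_density(
    vafs, bandwidth: float | None = None, grid_step: float = GRID_STEP
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of a VAF sample on a fixed grid over [0, 1].

    Mass falling outside [0, 1] is reflected back at both boundaries so
    clonal (VAF ~0.5 is interior) and near-zero tail peaks are not biased
    by edge truncation.  Bandwidth defaults to Silverman's rule.  Fewer
    than 10 VAFs raise a ValueError (insufficient mutations).
    """
    v = np.asarray(vafs, dtype=float)
    if v.size < MIN_MUTATIONS:
        raise ValueError(
            f"insufficient mutations for density estimation: {v.size} < {MIN_MUTATIONS}"
        )
    if ((v < 0) | (v > 1)).any():
        raise ValueError("VAFs must lie in [0, 1]")
    h = silverman_bandwidth(v) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    # reflection at 0 and 1: K(x - v) + K(x + v) + K(2 - x - v)
    def _k(x):
        z = (x[:, None] - v[None, :]) / h
        return np.exp(-0.5 * z * z).sum(axis=1)
    norm = 1.0 / (v.size * h * np.sqrt(2 * np.pi))
    dens = norm * (_k(grid) + _k(-grid) + _k(2.0 - grid))
    return grid, dens


def subclone_fraction(mean_vaf: float) -> float:
    """Cell-population fraction of a subclone from its cluster mean VAF.

    Diploid, copy-neutral, heterozygous model: a subclone occupying
    fraction f yields VAF f/2, so the inverse is min(1, 2·VAF); a cluster
    at VAF 0.25 marks a subclone spanning half the population and VAF 0.5
    a fully clonal population.
    """
    if not (0 <= mean_vaf <= 1):
        raise ValueError("mean_vaf must lie in [0, 1]")
    return min(1.0, 2.0 * float(mean_vaf))


def _local_extrema(dens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima of a curve (plateau-safe)."""
    d = np.sign(np.diff(dens))
    # carry the last non-zero slope through plateaus
    for i in range(1, d.size):
        if d[i] == 0:
            d[i] = d[i - 1]
    turns = np.diff(d)
    maxima = np.where(turns < 0)[0] + 1
    minima = np.where(turns > 0)[0] + 1
    return maxima, minima


def find_clusters(
    vafs,
    min_fraction: float = 0.10,
    bandwidth: float | None = None,
    grid_step: float = GRID_STEP,
) -> VAFClusterSet:
    """Identify subclonal VAF clusters from the smoothed distribution.

    Each local maximum of the density defines a cluster whose members are
    the mutations with VAF between the flanking local minima (the
    boundaries 0 and 1 close the outermost clusters).  Clusters holding
    fewer than ``min_fraction`` of all mutations are dropped.  A density
    with no interior maximum yields a single cluster spanning [0, 1].
    """
    v = np.asarray(vafs, dtype=float)
    grid, dens = estimate_density(v, bandwidth=bandwidth, grid_step=grid_step)
    h = silverman_bandwidth(v) if bandwidth is None else float(bandwidth)
    maxima, minima = _local_extrema(dens)
    if maxima.size == 0:
        edges = np.array([0.0, 1.0])
    else:
        cuts = [grid[m] for m in minima]
        edges = np.array([0.0] + cuts + [1.0])
    clusters: list[VAFCluster] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        member = (v >= lo) & (v < hi) if hi < 1.0 else (v >= lo) & (v <= hi)
        n = int(member.sum())
        if n == 0:
            continue
        frac = n / v.size
        mean = float(v[member].mean())
        clusters.append(
            VAFCluster(
                mean_vaf=mean,
                mutation_fraction=frac,
                subclone_fraction=subclone_fraction(mean),
                n_mutations=n,
                bounds=(float(lo), float(hi)),
            )
        )
    clusters = [c for c in clusters if c.mutation_fraction >= min_fraction]
    clusters.sort(key=lambda c: c.mean_vaf)
    return VAFClusterSet(
        clusters=clusters,
        bandwidth=h,
        n_mutations=v.size,
        grid=grid,
        density=dens,
    )


def classify_clonality(
    cluster_set: VAFClusterSet,
    clonal_tolerance: float = 0.10,
    tail_cutoff: float = 0.10,
) -> str:
    """Classify a sample clonal/oligoclonal from its VAF clusters.

    The near-zero neutral-tail cluster (mean VAF below ``tail_cutoff``) is
    excluded from the decision.  The sample is clonal when the largest
    remaining cluster sits within ``clonal_tolerance`` of VAF 0.5 —
    the expected value for heterozygous mutations carried by every cell —
    and oligoclonal otherwise; samples with only tail clusters are
    indeterminate.
    """
    non_tail = [c for c in cluster_set.clusters if c.mean_vaf >= tail_cutoff]
    if not non_tail:
        cluster_set.classification = "indeterminate"
        return "indeterminate"
    dominant = max(non_tail, key=lambda c: c.mutation_fraction)
    label = "clonal" if abs(dominant.mean_vaf - 0.5) <= clonal_tolerance else "oligoclonal"
    cluster_set.classification = label
    return label
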