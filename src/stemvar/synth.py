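"""Synthetic fibroblast/hiPSC lineage simulator.

Generates an oligoclonal parent cell population (shared-ancestor mutations,
per-subclone private mutations, a power-law neutral tail), derives clonal
daughter lines through a single-cell reprogramming bottleneck, adds
culture-acquired oxidative mutations proportional to passage number, and
samples paired read counts under a binomial sequencing model.  Matching
gene-footprint and replication-timing annotations and full ground-truth
records are produced for parameter-recovery testing.

Model assumptions
-----------------
* Diploid, copy-neutral genome; every somatic event is heterozygous, so the
  expected variant allele fraction (VAF) of a mutation carried by a cell
  fraction f is f/2.
* UV-process events are C>T at dipyrimidine-rich contexts (TCA/TCC/TCT
  dominated), a configurable fraction emitted as CC>TT doublets, with
  transcribed:nontranscribed placement odds 1:``strand_asymmetry`` inside
  gene footprints.
* Culture-process events are C>A at ACA/GCA/GCT-like contexts, Poisson in
  ``passages * culture_rate_per_passage``.
* The neutral tail has cell fractions with density proportional to 1/f^2,
  truncated to [2/depth_mean, 0.1].
* Sequencing depth is Poisson(``depth_mean``) with floor 1; alt reads are
  binomial in depth with success probability VAF adjusted by the per-base
  error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import sigfit
from .sigfit import CHANNELS, revcomp

__all__ = [
    "SimConfig",
    "TruthMutation",
    "AnnotationTracks",
    "simulate_parent_population",
    "simulate_derived_line",
    "sample_read_counts",
    "truth_frame",
    "truth_events",
]

@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated lineage experiment.

    Counts are expected event numbers (Poisson draws unless noted); all
    rates must be non-negative and subclone fractions must lie in (0, 1]
    and sum to at most 1.
    """

    seed: int = 0
    n_subclones: int = 2
    subclone_fractions: tuple[float, ...] = (0.5, 0.3)
    ancestral_mutations: int = 300
    uv_rate_per_subclone: float = 400.0
    doublet_fraction: float = 0.1
    culture_rate_per_passage: float = 15.0
    passages: int = 18
    neutral_tail_mutations: int = 300
    depth_mean: float = 41.0
    error_rate: float = 1e-3
    strand_asymmetry: float = 2.0
    n_genes: int = 200
    n_rt_bins: int = 5
    n_error_sites: int = 1000
    n_germline_sites: int = 30
    genome_length: int = 10_000_000
    gene_fraction: float = 0.5
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_subclones != len(self.subclone_fractions):
            raise ValueError("n_subclones must match len(subclone_fractions)")
        if any(not (0 < f <= 1) for f in self.subclone_fractions):
            raise ValueError("subclone fractions must lie in (0, 1]")
        if sum(self.subclone_fractions) > 1 + 1e-12:
            raise ValueError("subclone fractions must sum to <= 1")
        for name in (
            "uv_rate_per_subclone",
            "doublet_fraction",
            "culture_rate_per_passage",
            "neutral_tail_mutations",
            "error_rate",
            "ancestral_mutations",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.strand_asymmetry <= 0:
            raise ValueError("strand_asymmetry must be > 0")
        if not (0 <= self.doublet_fraction <= 1):
            raise ValueError("doublet_fraction must be in [0, 1]")
        if self.passages < 0:
            raise ValueError("passages must be >= 0")


@dataclass(frozen=True)
class TruthMutation:
    """One simulated somatic event on the reference + strand.

    ``ref``/``alt`` are single bases, or dinucleotides for the two-base
    records backing a CC>TT doublet member.  ``cell_fraction`` is the
    fraction of the sampled cell population carrying the event.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    context: str
    cell_fraction: float
    process: str  # UV | CULTURE | NEUTRAL | GERMLINE
    strand_of_origin: str  # transcribed | nontranscribed | intergenic
    rt_bin: int
    subclone: int | None = None
    doublet_id: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.cell_fraction <= 1):
            raise ValueError("cell_fraction must lie in (0, 1]")
        if self.ref == self.alt:
            raise ValueError("ref must differ from alt")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")


@dataclass(frozen=True)
class AnnotationTracks:
    """Gene footprints (with strand) and replication-timing bins.

    Intervals are half-open [start, end) with 1-based starts; the RT bins
    tile the whole simulated chromosome.
    """

    gene_footprints: pd.DataFrame  # chrom, start, end, strand, name
    rt_bins: pd.DataFrame  # chrom, start, end, bin


def truth_frame(muts: list[TruthMutation]) -> pd.DataFrame:
    """Tabulate ground-truth mutations as a DataFrame."""
    cols = [
        "chrom", "pos", "ref", "alt", "context", "cell_fraction",
        "process", "strand_of_origin", "rt_bin", "subclone", "doublet_id",
    ]
    if not muts:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(m) for m in muts], columns=cols)


def truth_events(muts: list[TruthMutation]) -> pd.DataFrame:
    """Tabulate truth with doublet members collapsed into CC>TT records.

    Single events keep ``mut_class`` "SNV"; the two adjacent members of a
    doublet become one "DBS" row at the first base's position with
    concatenated ref/alt (CC>TT or GG>AA).
    """
    df = truth_frame(muts)
    if df.empty:
        return df.assign(mut_class=pd.Series(dtype=object))
    singles = df[df["doublet_id"].isna()].copy()
    singles["mut_class"] = "SNV"
    rows = [singles]
    doublets = df[df["doublet_id"].notna()]
    if len(doublets):
        merged = []
        for _, pair in doublets.groupby("doublet_id"):
            pair = pair.sort_values("pos")
            first = pair.iloc[0].to_dict()
            first["ref"] = "".join(pair["ref"])
            first["alt"] = "".join(pair["alt"])
            first["mut_class"] = "DBS"
            merged.append(first)
        rows.append(pd.DataFrame(merged))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Annotation construction


def _make_annotations(config: SimConfig, rng: np.random.Generator) -> AnnotationTracks:
    L, n = config.genome_length, config.n_genes
    gene_len = int(L * config.gene_fraction / n)
    spacing = L // n
    starts = 1 + spacing * np.arange(n)
    strands = rng.choice(["+", "-"], size=n)
    genes = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": starts + gene_len,
            "strand": strands,
            "name": [f"GENE{i:04d}" for i in range(n)],
        }
    )
    edges = np.linspace(1, L + 1, config.n_rt_bins + 1).astype(int)
    rt = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": edges[:-1],
            "end": edges[1:],
            "bin": np.arange(config.n_rt_bins),
        }
    )
    return AnnotationTracks(gene_footprints=genes, rt_bins=rt)


class _Locator:
    """O(log n) strand/RT lookup over sorted non-overlapping tracks."""

    def __init__(self, tracks: AnnotationTracks):
        g = tracks.gene_footprints.sort_values("start")
        self.g_start = g["start"].to_numpy()
        self.g_end = g["end"].to_numpy()
        self.g_strand = g["strand"].to_numpy()
        r = tracks.rt_bins.sort_values("start")
        self.r_start = r["start"].to_numpy()
        self.r_end = r["end"].to_numpy()
        self.r_bin = r["bin"].to_numpy()

    def __call__(self, pos: int) -> tuple[str | None, int]:
        strand = None
        i = int(np.searchsorted(self.g_start, pos, side="right")) - 1
        if i >= 0 and pos < self.g_end[i]:
            strand = str(self.g_strand[i])
        rt_bin = -1
        j = int(np.searchsorted(self.r_start, pos, side="right")) - 1
        if j >= 0 and pos < self.r_end[j]:
            rt_bin = int(self.r_bin[j])
        return strand, rt_bin


class _PositionPool:
    """Draws unique 1-based positions (pairs for doublets) without reuse."""

    def __init__(self, length: int, rng: np.random.Generator):
        self.length = length
        self.rng = rng
        self.used: set[int] = set()

    def draw(self, width: int = 1) -> int:
        for _ in range(10_000):
            pos = int(self.rng.integers(1, self.length - width + 1))
            span = range(pos, pos + width)
            if all(p not in self.used for p in span):
                self.used.update(span)
                return pos
        raise RuntimeError("position pool exhausted; increase genome_length")

    def reserve(self, positions) -> None:
        self.used.update(int(p) for p in positions)


def _draw_channel(profile: np.ndarray, rng: np.random.Generator) -> tuple[str, str, str]:
    """Sample (ref, alt, context) in pyrimidine orientation from a 96-profile."""
    label = CHANNELS[int(rng.choice(96, p=profile))]
    five, sub, three = label[0], label[2:5], label[6]
    return sub[0], sub[2], five + sub[0] + three


def _orient_to_strand(
    ref: str, alt: str, context: str, pyrimidine_on_plus: bool
) -> tuple[str, str, str]:
    """Place a pyrimidine-oriented event so its pyrimidine sits on +/- strand."""
    if pyrimidine_on_plus:
        return ref, alt, context
    return revcomp(ref), revcomp(alt), revcomp(context)


def _uv_strand_choice(
    gene_strand: str | None, asymmetry: float, rng: np.random.Generator
) -> tuple[str, bool]:
    """UV event strand label and whether its pyrimidine lies on the + strand.

    Inside a gene the nontranscribed (coding) strand is chosen with odds
    ``asymmetry`` : 1 over the transcribed (template) strand; the
    nontranscribed case puts the pyrimidine on the gene's own strand.
    """
    if gene_strand is None:
        return "intergenic", bool(rng.integers(2))
    p_nontrans = asymmetry / (1.0 + asymmetry)
    if rng.random() < p_nontrans:
        return "nontranscribed", gene_strand == "+"
    return "transcribed", gene_strand == "-"


def _neutral_fractions(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    # density ~ 1/f^2 truncated to [2/depth_mean, 0.1]; inverse-CDF sampling
    a = min(2.0 / config.depth_mean, 0.1)
    b = 0.1
    if a >= b:
        return np.full(n, b)
    u = rng.random(n)
    return 1.0 / (1.0 / a - u * (1.0 / a - 1.0 / b))


# ---------------------------------------------------------------------------
# Operations


def _emit_uv_events(
    n_events: int,
    cell_fraction: float,
    subclone: int | None,
    config: SimConfig,
    locate: "_Locator",
    pool: _PositionPool,
    rng: np.random.Generator,
    uv_profile: np.ndarray,
    doublet_counter: list[int],
) -> list[TruthMutation]:
    out: list[TruthMutation] = []
    for _ in range(n_events):
        is_doublet = rng.random() < config.doublet_fraction
        width = 2 if is_doublet else 1
        pos = pool.draw(width)
        gene_strand, rt_bin = locate(pos)
        strand_label, pyr_plus = _uv_strand_choice(
            gene_strand, config.strand_asymmetry, rng
        )
        if is_doublet:
            doublet_counter[0] += 1
            did = doublet_counter[0]
            # CC>TT on the pyrimidine strand, recorded base-by-base on +
            for offset in range(2):
                ref, alt = ("C", "T") if pyr_plus else ("G", "A")
                ctx = ("CCC" if pyr_plus else "GGG")
                out.append(
                    TruthMutation(
                        chrom=config.chrom,
                        pos=pos + offset,
                        ref=ref,
                        alt=alt,
                        context=ctx,
                        cell_fraction=cell_fraction,
                        process="UV",
                        strand_of_origin=strand_label,
                        rt_bin=rt_bin,
                        subclone=subclone,
                        doublet_id=did,
                    )
                )
        else:
            ref, alt, ctx = _draw_channel(uv_profile, rng)
            ref, alt, ctx = _orient_to_strand(ref, alt, ctx, pyr_plus)
            out.append(
                TruthMutation(
                    chrom=config.chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    context=ctx,
                    cell_fraction=cell_fraction,
                    process="UV",
                    strand_of_origin=strand_label,
                    rt_bin=rt_bin,
                    subclone=subclone,
                )
            )
    return out


def _emit_simple_events(
    n_events: int,
    cell_fractions: np.ndarray,
    process: str,
    profile: np.ndarray,
    config: SimConfig,
    locate: "_Locator",
    pool: _PositionPool,
    rng: np.random.Generator,
) -> list[TruthMutation]:
    out: list[TruthMutation] = []
    for i in range(n_events):
        pos = pool.draw()
        gene_strand, rt_bin = locate(pos)
        pyr_plus = bool(rng.integers(2))
        if gene_strand is None:
            strand_label = "intergenic"
        elif (gene_strand == "+") == pyr_plus:
            strand_label = "nontranscribed"
        else:
            strand_label = "transcribed"
        ref, alt, ctx = _draw_channel(profile, rng)
        ref, alt, ctx = _orient_to_strand(ref, alt, ctx, pyr_plus)
        out.append(
            TruthMutation(
                chrom=config.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                context=ctx,
                cell_fraction=float(cell_fractions[i]),
                process=process,
                strand_of_origin=strand_label,
                rt_bin=rt_bin,
            )
        )
    return out


def simulate_parent_population(
    config: SimConfig,
) -> tuple[list[TruthMutation], AnnotationTracks]:
    """Simulate the oligoclonal parent (fibroblast) cell population.

    Emits shared-ancestor mutations at cell fraction 1, UV-process
    mutations private to each subclone at that subclone's fraction, a
    neutral low-frequency tail, and heterozygous germline-like sites
    (cell fraction 1 in parent and any derived line) used to exercise the
    caller's germline prefilter.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    tracks = _make_annotations(config, rng)
    locate = _Locator(tracks)
    pool = _PositionPool(config.genome_length, rng)
    uv_profile = sigfit.fallback_signatures().matrix["UVlike"].to_numpy()
    flat = np.full(96, 1.0 / 96)
    doublet_counter = [0]

    muts: list[TruthMutation] = []
    # Shared most-recent-common-ancestor mutations: in-vivo UV process.
    muts += _emit_uv_events(
        config.ancestral_mutations, 1.0, None, config, locate, pool, rng,
        uv_profile, doublet_counter,
    )
    # Private UV burden of each subclone lineage.
    for i, frac in enumerate(config.subclone_fractions):
        n_uv = int(rng.poisson(config.uv_rate_per_subclone))
        muts += _emit_uv_events(
            n_uv, float(frac), i, config, locate, pool, rng, uv_profile,
            doublet_counter,
        )
    # Neutral tail.
    fracs = _neutral_fractions(config.neutral_tail_mutations, config, rng)
    muts += _emit_simple_events(
        config.neutral_tail_mutations, fracs, "NEUTRAL", flat, config,
        locate, pool, rng,
    )
    # Germline-like heterozygous sites (population-frequency prefilter fodder).
    muts += _emit_simple_events(
        config.n_germline_sites, np.ones(config.n_germline_sites), "GERMLINE",
        flat, config, locate, pool, rng,
    )
    return muts, tracks


def simulate_derived_line(
    parent_truth: list[TruthMutation],
    config: SimConfig,
    subclone_index: int,
    seed: int,
) -> list[TruthMutation]:
    """Derive one clonal line from a single cell of the chosen subclone.

    The line inherits the shared-ancestor mutations, the chosen subclone's
    private mutations and the germline-like sites, all clonal (cell
    fraction 1), and acquires new oxidative culture mutations with expected
    count ``passages * culture_rate_per_passage``, also clonal.
    """
    if not (0 <= subclone_index < config.n_subclones):
        raise ValueError(
            f"subclone_index {subclone_index} out of range 0..{config.n_subclones - 1}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tracks = _make_annotations(
        config, np.random.default_rng(np.random.SeedSequence(config.seed))
    )
    locate = _Locator(tracks)
    inherited = [
        replace(m, cell_fraction=1.0)
        for m in parent_truth
        if (m.process == "GERMLINE")
        or (m.subclone is None and m.process == "UV")
        or (m.subclone == subclone_index)
    ]
    pool = _PositionPool(config.genome_length, rng)
    pool.reserve(m.pos for m in parent_truth)
    culture_profile = sigfit.fallback_signatures().matrix["Oxidative"].to_numpy()
    n_culture = int(rng.poisson(config.passages * config.culture_rate_per_passage))
    culture = _emit_simple_events(
        n_culture, np.ones(n_culture), "CULTURE", culture_profile, config,
        locate, pool, rng,
    )
    return inherited + culture


def sample_read_counts(
    parent_truth: list[TruthMutation],
    derived_truth: list[TruthMutation],
    config: SimConfig,
    seed: int,
) -> pd.DataFrame:
    """Sample paired per-site read counts for parent and derived samples.

    Every truth site in either sample is emitted, plus ``n_error_sites``
    error-only sites carried by neither.  Depth is Poisson(depth_mean) with
    floor 1 per sample; alt reads are binomial with success probability
    ``vaf*(1-e) + (1-vaf)*e`` where vaf = cell_fraction/2 and e is the
    per-base error rate.  Identical inputs and seed give identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    parent_by_site = {(m.chrom, m.pos): m for m in parent_truth}
    derived_by_site = {(m.chrom, m.pos): m for m in derived_truth}
    sites = sorted(set(parent_by_site) | set(derived_by_site))

    pool = _PositionPool(config.genome_length, rng)
    pool.reserve(pos for _, pos in sites)
    error_sites = []
    flat = np.full(96, 1.0 / 96)
    for _ in range(config.n_error_sites):
        pos = pool.draw()
        ref, alt, ctx = _draw_channel(flat, rng)
        error_sites.append((config.chrom, pos, ref, alt, ctx))

    rows = []
    e = config.error_rate

    def _counts(cell_fraction: float) -> tuple[int, int]:
        depth = max(1, int(rng.poisson(config.depth_mean)))
        vaf = cell_fraction / 2.0
        p = vaf * (1 - e) + (1 - vaf) * e
        alt = int(rng.binomial(depth, p))
        return depth - alt, alt

    for chrom, pos in sites:
        m = parent_by_site.get((chrom, pos)) or derived_by_site[(chrom, pos)]
        p_cf = parent_by_site[(chrom, pos)].cell_fraction if (chrom, pos) in parent_by_site else 0.0
        d_cf = derived_by_site[(chrom, pos)].cell_fraction if (chrom, pos) in derived_by_site else 0.0
        p_ref, p_alt = _counts(p_cf)
        d_ref, d_alt = _counts(d_cf)
        rows.append(
            (chrom, pos, m.ref, m.alt, m.context, p_ref, p_alt, d_ref, d_alt,
             m.process == "GERMLINE")
        )
    for chrom, pos, ref, alt, ctx in error_sites:
        p_ref, p_alt = _counts(0.0)
        d_ref, d_alt = _counts(0.0)
        rows.append((chrom, pos, ref, alt, ctx, p_ref, p_alt, d_ref, d_alt, False))

    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "context",
            "parent_ref", "parent_alt", "derived_ref", "derived_alt",
            "germline_flag",
        ],
    )
    df["mask_low_mappability"] = False
    df["mask_cnv"] = False
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
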