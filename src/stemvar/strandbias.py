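"""Transcriptional strand bias of C>T / CC>TT events by replication timing.

UV photoproducts form at dipyrimidines; transcription-coupled repair
preferentially clears lesions from the transcribed (template) strand, so
UV-exposed genomes show an excess of C>T and CC>TT on the nontranscribed
strand.  This module assigns each pyrimidine-oriented event to the
transcribed or nontranscribed strand using protein-coding gene footprints
and their transcription direction, stratifies counts by replication-timing
bin, and reports per-bin asymmetry ratios.

Conventions: intervals are half-open [start, end) with 1-based starts;
positions covered by gene footprints on both strands are ambiguous and
excluded (but counted); a CC>TT doublet is assigned by its first base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["StrandRTTable", "assign_strand", "tabulate"]

STRANDS = ("transcribed", "nontranscribed")
MUT_TYPES = ("C>T", "CC>TT")
_PYRIMIDINE_REF = {"C": "+", "T": "+", "G": "-", "A": "-"}


def _build_trees(intervals: pd.DataFrame, value_col: str) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (ends < starts).any():
            raise ValueError(f"malformed interval on {chrom}: end < start")
        tree = IntervalTree()
        for s, e, v in zip(starts, ends, sub[value_col]):
            if e > s:
                tree.addi(int(s), int(e), v)
        trees[chrom] = tree
    return trees


def assign_strand(
    chrom: str, pos: int, ref: str, gene_trees: dict[str, IntervalTree]
) -> str:
    """Strand category of a pyrimidine-oriented substitution.

    Within a gene footprint: when the mutated pyrimidine lies on the gene's
    own (coding, nontranscribed) strand the event is "nontranscribed", and
    when it lies on the template strand it is "transcribed".  ``ref`` is
    the reference base on the + strand, so a C or T ref puts the pyrimidine
    on +, a G or A ref on -.  Positions outside all footprints are
    "intergenic"; positions inside footprints of both orientations are
    "ambiguous".
    """
    base = ref[0].upper()
    if base not in _PYRIMIDINE_REF:
        raise ValueError(f"invalid reference base {ref!r} at {chrom}:{pos}")
    tree = gene_trees.get(chrom)
    hits = {iv.data for iv in tree.overlap(pos, pos + 1)} if tree is not None else set()
    if not hits:
        return "intergenic"
    if len(hits) > 1:
        return "ambiguous"
    gene_strand = next(iter(hits))
    pyr_strand = _PYRIMIDINE_REF[base]
    return "nontranscribed" if pyr_strand == gene_strand else "transcribed"


@dataclass
class StrandRTTable:
    """Strand-by-replication-timing counts of C>T and CC>TT events.

    ``counts`` is indexed by (mut_type, strand, rt_bin); ``excluded``
    counts intergenic/ambiguous/unbinned events per mutation type, and
    ``ratios`` gives the per-bin nontranscribed/transcribed ratio (NaN
    when the denominator is zero).
    """

    counts: pd.Series
    excluded: pd.DataFrame
    ratios: pd.DataFrame

    def total(self, mut_type: str) -> int:
        strand_total = int(self.counts.xs(mut_type, level="mut_type").sum())
        return strand_total + int(self.excluded.loc[mut_type, ["intergenic", "ambiguous"]].sum())


def _mut_type(ref: str, alt: str) -> str | None:
    """Pyrimidine-oriented label of an event, restricted to C>T / CC>TT."""
    ref, alt = ref.upper(), alt.upper()
    if (ref, alt) in (("C", "T"), ("G", "A")):
        return "C>T"
    if (ref, alt) in (("CC", "TT"), ("GG", "AA")):
        return "CC>TT"
    return None


def tabulate(
    mutations: pd.DataFrame,
    gene_footprints: pd.DataFrame,
    rt_bins: pd.DataFrame,
) -> StrandRTTable:
    """Count C>T and CC>TT events by strand and replication-timing bin.

    ``mutations`` needs chrom/pos/ref/alt columns; other substitution types
    are ignored.  Every C>T or CC>TT increments exactly one cell: a
    (mut_type, strand, rt_bin) cell for genic unambiguous events (with bin
    -1 as the "unbinned" stratum for positions no RT interval covers), or
    the intergenic/ambiguous exclusion tallies.
    """
    gene_trees = _build_trees(gene_footprints, "strand")
    rt_trees = _build_trees(rt_bins, "bin")
    bins = sorted(set(rt_bins["bin"])) + [-1]
    index = pd.MultiIndex.from_product(
        [MUT_TYPES, STRANDS, bins], names=["mut_type", "strand", "rt_bin"]
    )
    counts = pd.Series(0, index=index, dtype=int)
    excluded = pd.DataFrame(
        0, index=list(MUT_TYPES), columns=["intergenic", "ambiguous"], dtype=int
    )
    for chrom, pos, ref, alt in zip(
        mutations["chrom"], mutations["pos"], mutations["ref"], mutations["alt"]
    ):
        mt = _mut_type(str(ref), str(alt))
        if mt is None:
            continue
        pos = int(pos)
        strand = assign_strand(chrom, pos, str(ref), gene_trees)
        if strand in ("intergenic", "ambiguous"):
            excluded.loc[mt, strand] += 1
            continue
        tree = rt_trees.get(chrom)
        hits = {iv.data for iv in tree.overlap(pos, pos + 1)} if tree is not None else set()
        rt_bin = int(next(iter(hits))) if len(hits) == 1 else -1
        counts.loc[(mt, strand, rt_bin)] += 1
    ratio_rows = {}
    for mt in MUT_TYPES:
        row = {}
        for b in bins:
            nt = counts.loc[(mt, "nontranscribed", b)]
            t = counts.loc[(mt, "transcribed", b)]
            row[b] = nt / t if t > 0 else np.nan
        ratio_rows[mt] = row
    ratios = pd.DataFrame(ratio_rows).T
    ratios.index.name = "mut_type"
    return StrandRTTable(counts=counts, excluded=excluded, ratios=ratios)
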