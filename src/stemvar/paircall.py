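"""Paired-sample somatic variant calling by per-site Fisher exact tests.

Given per-site reference/alternate read counts in a parent (fibroblast or
erythroblast) sample and a derived (hiPSC or subclone) sample, a two-sided
Fisher exact test on the 2x2 table

    [[parent_ref, parent_alt],
     [derived_ref, derived_alt]]

detects a significant change in allele frequency between the samples —
deliberately symmetric rather than tumour-normal style, since mutations of
interest may be present at low frequency in the parent tissue.  Sites are
prefiltered on depth, alternate support and a germline exclusion flag,
corrected genome-wide by Benjamini–Hochberg, postfiltered on VAF <= 0.6 and
mappability/copy-number masks, merged into dinucleotide (DBS) and longer
(MNV) records, and classified shared/private by parent alternate support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the paired caller.

    Defaults: minimum depth 20 reads in both samples, at least 3 alternate
    reads in either sample, a 5% false discovery rate, and a postfilter
    removing sites above 0.6 alternate allele frequency in either sample.
    """

    min_depth: int = 20
    min_alt: int = 3
    fdr: float = 0.05
    max_vaf: float = 0.6
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_alt <= 0:
            raise ValueError("min_depth and min_alt must be positive")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if not (0 < self.max_vaf <= 1):
            raise ValueError("max_vaf must lie in (0, 1]")


class CallResult(NamedTuple):
    calls: pd.DataFrame
    bh_threshold: float
    n_tested: int


def prefilter_sites(sites: pd.DataFrame, config: CallerConfig = CallerConfig()) -> pd.DataFrame:
    """Drop germline-flagged, low-depth and low-alternate-support sites.

    Retains sites with depth (ref+alt) >= ``min_depth`` in both samples and
    at least ``min_alt`` alternate reads in either sample; input order is
    preserved.  Low-coverage sites could never reach significance, so
    excluding them also keeps the multiple-testing burden honest.
    """
    if len(sites) == 0:
        return sites.copy()
    p_depth = sites["parent_ref"] + sites["parent_alt"]
    d_depth = sites["derived_ref"] + sites["derived_alt"]
    keep = (
        ~sites.get("germline_flag", pd.Series(False, index=sites.index)).astype(bool)
        & (p_depth >= config.min_depth)
        & (d_depth >= config.min_depth)
        & (sites[["parent_alt", "derived_alt"]].max(axis=1) >= config.min_alt)
    )
    return sites[keep].copy()


def fisher_site_test(
    parent_ref: int, parent_alt: int, derived_ref: int, derived_alt: int,
    two_sided: bool = True,
) -> float:
    """Fisher exact p-value for one site's 2x2 allele-count table.

    All-zero tables return 1 by convention.  The one-sided alternative
    tests for alternate-allele enrichment in the derived sample.
    """
    table = np.array([[parent_ref, parent_alt], [derived_ref, derived_alt]])
    if (table < 0).any():
        raise ValueError("read counts must be non-negative")
    if table.sum() == 0:
        return 1.0
    # one-sided: derived alternate enrichment, i.e. large odds ratio of
    # (parent_ref * derived_alt) / (parent_alt * derived_ref)
    alternative = "two-sided" if two_sided else "greater"
    return float(fisher_exact(table, alternative=alternative).pvalue)


def fisher_table_pvalues(sites: pd.DataFrame, two_sided: bool = True) -> np.ndarray:
    """Vector of Fisher p-values over the rows of a counts table."""
    cache: dict[tuple[int, int, int, int], float] = {}
    out = np.empty(len(sites))
    cols = ["parent_ref", "parent_alt", "derived_ref", "derived_alt"]
    for i, key in enumerate(map(tuple, sites[cols].itertuples(index=False))):
        p = cache.get(key)
        if p is None:
            p = cache[key] = fisher_site_test(*key, two_sided=two_sided)
        out[i] = p
    return out


def bh_correct(p_values, fdr: float = 0.05) -> tuple[float, np.ndarray]:
    """Benjamini–Hochberg step-up control at the given FDR.

    Returns the data-dependent p-value threshold (the largest p(k) with
    p(k) <= (k/m)·fdr; 0 when nothing qualifies) and per-test significance
    flags.  Ties at the threshold are all significant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return 0.0, np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return threshold, p <= threshold if threshold > 0 else reject


def postfilter_calls(calls: pd.DataFrame, config: CallerConfig = CallerConfig()) -> pd.DataFrame:
    """Remove high-VAF (likely germline/artefact) and masked calls.

    Drops calls whose VAF exceeds ``max_vaf`` in either sample — such sites
    are enriched for false positives — and calls flagged by the
    low-mappability or copy-number-overlap masks.
    """
    if len(calls) == 0:
        return calls.copy()
    keep = (
        (calls["parent_vaf"] <= config.max_vaf)
        & (calls["derived_vaf"] <= config.max_vaf)
        & ~calls.get("mask_low_mappability", pd.Series(False, index=calls.index)).astype(bool)
        & ~calls.get("mask_cnv", pd.Series(False, index=calls.index)).astype(bool)
    )
    return calls[keep].copy()


def classify_shared_private(
    calls: pd.DataFrame, parent_counts: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flag each call shared (>=1 parent alternate read) or private (0).

    When ``parent_counts`` is given, parent alternate support is joined on
    (chrom, pos); a call site missing from it raises an error naming the
    site.  Otherwise the calls' own ``parent_alt`` column is used.
    """
    calls = calls.copy()
    if parent_counts is not None:
        lookup = parent_counts.set_index(["chrom", "pos"])["parent_alt"]
        alts = []
        for chrom, pos in zip(calls["chrom"], calls["pos"]):
            try:
                alts.append(int(lookup.loc[(chrom, pos)]))
            except KeyError:
                raise KeyError(f"no parent record at site {chrom}:{pos}") from None
        calls["shared"] = np.asarray(alts) >= 1
    else:
        calls["shared"] = calls["parent_alt"] >= 1
    return calls


def merge_dinucleotides(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of adjacent calls into DBS/MNV records.

    Calls are sorted by (chrom, pos); maximal runs of consecutive positions
    of length 2 become one DBS record with concatenated ref/alt (e.g.
    CC>TT), length >= 3 one MNV record; isolated calls stay SNV.  Merged
    records keep the first position, the smallest member p-value, the mean
    member VAFs and are shared if any member is.
    """
    if len(calls) == 0:
        out = calls.copy()
        out["mut_class"] = pd.Series(dtype=object)
        return out
    calls = calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    new_run = (calls["chrom"] != calls["chrom"].shift()) | (
        calls["pos"] != calls["pos"].shift() + 1
    )
    run_id = new_run.cumsum()
    merged = []
    for _, run in calls.groupby(run_id, sort=False):
        first = run.iloc[0].to_dict()
        if len(run) == 1:
            first["mut_class"] = "SNV"
        else:
            first["mut_class"] = "DBS" if len(run) == 2 else "MNV"
            first["ref"] = "".join(run["ref"])
            first["alt"] = "".join(run["alt"])
            if "p_value" in run:
                first["p_value"] = float(run["p_value"].min())
            for col in ("parent_vaf", "derived_vaf"):
                if col in run:
                    first[col] = float(run[col].mean())
            if "shared" in run:
                first["shared"] = bool(run["shared"].any())
        merged.append(first)
    return pd.DataFrame(merged).reset_index(drop=True)


def call_variants(
    sites: pd.DataFrame, config: CallerConfig = CallerConfig()
) -> CallResult:
    """Run the full paired caller on a counts table.

    Pipeline: prefilter -> per-site Fisher test -> genome-wide BH control
    over the whole tested batch -> VAF/mask postfilter -> shared/private
    classification -> dinucleotide merge.  Returns the significant calls,
    the BH p-value threshold and the number of tested sites.
    """
    tested = prefilter_sites(sites, config)
    if len(tested) == 0:
        empty = tested.assign(
            p_value=pd.Series(dtype=float), significant=pd.Series(dtype=bool)
        )
        return CallResult(calls=empty, bh_threshold=0.0, n_tested=0)
    tested = tested.copy()
    tested["p_value"] = fisher_table_pvalues(tested, two_sided=config.two_sided)
    threshold, flags = bh_correct(tested["p_value"].to_numpy(), config.fdr)
    tested["significant"] = flags
    calls = tested[tested["significant"]].copy()
    calls["parent_vaf"] = calls["parent_alt"] / (calls["parent_ref"] + calls["parent_alt"])
    calls["derived_vaf"] = calls["derived_alt"] / (
        calls["derived_ref"] + calls["derived_alt"]
    )
    calls = postfilter_calls(calls, config)
    calls = classify_shared_private(calls)
    calls = merge_dinucleotides(calls)
    return CallResult(calls=calls, bh_threshold=threshold, n_tested=len(tested))
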