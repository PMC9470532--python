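"""Cohort-level statistics for stem-cell line collections.

Gene-hit prevalence (exact binomial tests against a background cohort
rate), mutation-burden-versus-genotype comparisons (Mann–Whitney),
passage-versus-signature-exposure correlation (Pearson), sister-pair
heterogeneity (shared-mutation counts and catalog cosine similarity),
cancer-gene-census overlap, and parent-to-subclone variant tracking by
read-level presence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sigfit import cosine_similarity

__all__ = [
    "binomial_prevalence_test",
    "burden_vs_group_test",
    "passage_exposure_correlation",
    "pair_heterogeneity",
    "driver_overlap",
    "track_subclones",
    "SubcloneMatrix",
    "PairComparison",
]

EXACT_MW_MAX_N = 12


def binomial_prevalence_test(
    k_observed: int, n: int, p_background: float, alternative: str = "greater"
) -> float:
    """Exact binomial test of a cohort's gene-hit prevalence.

    Tests k hits among n lines against a background hit probability, e.g.
    a blood-derived cohort's prevalence against the fibroblast-derived
    rate.  Default alternative is "greater" (enrichment); "two-sided" and
    "less" are also accepted.
    """
    if not (0 <= k_observed <= n):
        raise ValueError("k_observed must lie in [0, n]")
    if not (0 < p_background < 1):
        raise ValueError("p_background must lie in (0, 1)")
    return float(
        stats.binomtest(k_observed, n, p_background, alternative=alternative).pvalue
    )


def burden_vs_group_test(burdens: Sequence[float], group_labels: Sequence) -> float:
    """Two-sided Mann–Whitney test of mutation burden between two groups.

    Uses exact enumeration when the combined sample size is at most 12 and
    there are no ties, and the normal approximation with tie correction
    otherwise.
    """
    burdens = np.asarray(burdens, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    x = burdens[labels == groups[0]]
    y = burdens[labels == groups[1]]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(burdens).size < burdens.size
    method = "exact" if (x.size + y.size <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def passage_exposure_correlation(
    records: pd.DataFrame, signature_name: str
) -> tuple[float, float]:
    """Pearson correlation between passage number and signature exposure.

    ``records`` needs a ``passage`` column and either a column named after
    the signature or an ``exposure_<name>`` column.  Returns (r, p) from
    the two-sided t transform; zero variance in either variable yields
    (nan, nan).
    """
    col = signature_name if signature_name in records.columns else f"exposure_{signature_name}"
    if col not in records.columns:
        raise KeyError(f"no exposure column for signature {signature_name!r}")
    sub = records[["passage", col]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 records with passage and exposure")
    x = sub["passage"].to_numpy(dtype=float)
    y = sub[col].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


class PairComparison(NamedTuple):
    n_shared: int
    cosine: float
    concordant: bool


def pair_heterogeneity(
    line_a_calls: pd.DataFrame,
    line_b_calls: pd.DataFrame,
    catalog_a: pd.Series,
    catalog_b: pd.Series,
    min_shared: int = 10,
    min_cosine: float = 0.9,
) -> PairComparison:
    """Compare two sister lines derived from one parent population.

    Counts identical (chrom, pos, ref, alt) substitution calls and the
    cosine similarity of the two SBS96 catalogs; the pair is concordant
    when it shares more than ``min_shared`` substitutions with cosine above
    ``min_cosine`` — the regime of lines reprogrammed from the same
    parental subclone.
    """
    if catalog_a is None or catalog_b is None:
        raise ValueError("both catalogs are required")
    key = ["chrom", "pos", "ref", "alt"]

    def _snv_keys(calls: pd.DataFrame) -> set[tuple]:
        rows = calls
        if "mut_class" in rows.columns:
            rows = rows[rows["mut_class"] == "SNV"]
        return set(map(tuple, rows[key].itertuples(index=False)))

    n_shared = len(_snv_keys(line_a_calls) & _snv_keys(line_b_calls))
    cos = cosine_similarity(catalog_a, catalog_b)
    return PairComparison(
        n_shared=n_shared,
        cosine=cos,
        concordant=(n_shared > min_shared and cos > min_cosine),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def prevalence_percent(k: int, n: int, decimals: int = 0) -> float:
    """Cohort prevalence k/n as a percentage, rounded half away from zero."""
    if n <= 0 or not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n with n > 0")
    scale = 10**decimals
    return _round_half_away(100.0 * k / n * scale) / scale


def driver_overlap(
    gene_hits_by_line: Mapping[str, Sequence[str]], census_genes: Sequence[str]
) -> tuple[dict[str, set[str]], int]:
    """Census-gene hits per line and the integer cohort hit percentage.

    A line is a hit-line when at least one of its calls falls in a census
    gene; the percentage of hit-lines is rounded half away from zero.
    """
    census = set(census_genes)
    if not census:
        raise ValueError("census gene list is empty")
    hits = {line: set(genes) & census for line, genes in gene_hits_by_line.items()}
    n_lines = len(hits)
    n_hit = sum(1 for h in hits.values() if h)
    pct = _round_half_away(100.0 * n_hit / n_lines) if n_lines else 0
    return hits, pct


@dataclass
class SubcloneMatrix:
    """Read-level presence of tracked variants across parent and subclones.

    ``presence`` is a variants x samples table: True when at least one
    alternate read supports the variant, False when zero reads do, and NA
    when no counts were available for that sample at that site.
    ``classification`` per variant: "recapitulated" (present in parent and
    >=1 subclone), "new_in_subclone" (zero parent alternate reads, present
    in >=1 subclone), "absent" (present in no subclone), or
    "unclassified" when parent counts are unavailable but a subclone
    carries the variant.
    """

    parent_id: str
    presence: pd.DataFrame
    classification: pd.Series

    def summary(self) -> dict[str, int]:
        return self.classification.value_counts().to_dict()


def _presence_lookup(counts: pd.DataFrame) -> dict[tuple, int]:
    key = ["chrom", "pos", "ref", "alt"]
    return {
        tuple(k): int(a)
        for *k, a in counts[key + ["alt_reads"]].itertuples(index=False)
    }


def track_subclones(
    parent_counts: pd.DataFrame,
    subclone_counts_by_sample: Mapping[str, pd.DataFrame],
    parent_id: str = "parent",
) -> SubcloneMatrix:
    """Track variants from a parental line into its daughter subclones.

    Inputs are per-sample tables with chrom/pos/ref/alt/alt_reads columns;
    tracked variants are the union over all samples.  Presence means at
    least one alternate read; a sample with no record at a tracked site is
    marked unavailable (NA).
    """
    lookups = {parent_id: _presence_lookup(parent_counts)}
    for name, counts in subclone_counts_by_sample.items():
        lookups[name] = _presence_lookup(counts)
    variants = sorted(set().union(*[set(lk) for lk in lookups.values()]))
    samples = [parent_id] + list(subclone_counts_by_sample)
    data = {
        sample: [
            (lookups[sample][v] >= 1) if v in lookups[sample] else pd.NA
            for v in variants
        ]
        for sample in samples
    }
    idx = pd.MultiIndex.from_tuples(variants, names=["chrom", "pos", "ref", "alt"])
    presence = pd.DataFrame(data, index=idx, dtype="boolean")
    sub_cols = list(subclone_counts_by_sample)
    labels = []
    for v in variants:
        parent_state = presence.loc[v, parent_id]
        in_any_sub = bool((presence.loc[v, sub_cols] == True).any())  # noqa: E712
        if not in_any_sub:
            labels.append("absent")
        elif parent_state is pd.NA:
            labels.append("unclassified")
        elif parent_state:
            labels.append("recapitulated")
        else:
            labels.append("new_in_subclone")
    classification = pd.Series(labels, index=idx, name="classification")
    return SubcloneMatrix(
        parent_id=parent_id, presence=presence, classification=classification
    )
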