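"""Mutational-signature catalogs and exposure fitting.

Builds pyrimidine-oriented 96-channel single-base-substitution (SBS96)
catalogs and decomposes them into non-negative combinations of reference
signatures by non-negative least squares (NNLS), with a multinomial
bootstrap to zero out unstable signatures.  Double/multi-nucleotide
substitutions are excluded from catalogs.

The 96 channels are ordered by substitution class (C>A, C>G, C>T, T>A,
T>C, T>G) and, within each class, by the 16 trinucleotide contexts in
lexicographic order of (5' base, 3' base).  Channel labels look like
``T[C>T]A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical SBS96 channel labels, e.g. ``A[C>A]A`` ... ``T[T>G]T``.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence {seq!r}") from exc


def orient_pyrimidine(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Return (ref, alt, context) with the mutated base as a pyrimidine.

    Purine-reference substitutions (G>A etc.) are reverse complemented,
    mutation and context together, so e.g. G>A at T[G]A becomes C>T at
    T[C]A.  Applying the orientation twice is the identity.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
        raise ValueError(f"malformed trinucleotide context {context!r}")
    if context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if ref in ("C", "T"):
        return ref, alt, context
    return _COMPLEMENT[ref], _COMPLEMENT[alt], revcomp(context)


def channel_of(ref: str, alt: str, context: str) -> str:
    """SBS96 channel label for a substitution with its context."""
    ref, alt, context = orient_pyrimidine(ref, alt, context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in _CHANNEL_INDEX:
        raise ValueError(f"invalid channel {label!r}")
    return label


def build_catalog(snv_calls: pd.DataFrame, sample_id: str = "sample") -> pd.Series:
    """Bin single-base substitutions into an SBS96 catalog.

    ``snv_calls`` needs columns ``ref``, ``alt`` and ``context`` (the
    reference-strand trinucleotide around the site).  Rows whose
    ``mut_class`` is present and not ``"SNV"`` (DBS/MNV records) are
    excluded.  Each remaining substitution increments exactly one channel,
    so the catalog sum equals the oriented SNV count.
    """
    counts = pd.Series(0, index=list(CHANNELS), name=sample_id, dtype=int)
    if len(snv_calls) == 0:
        return counts
    rows = snv_calls
    if "mut_class" in rows.columns:
        rows = rows[rows["mut_class"] == "SNV"]
    for chrom, pos, ref, alt, context in zip(
        rows.get("chrom", pd.Series(["?"] * len(rows))),
        rows.get("pos", pd.Series([0] * len(rows))),
        rows["ref"],
        rows["alt"],
        rows["context"],
    ):
        try:
            counts[channel_of(ref, alt, context)] += 1
        except ValueError as exc:
            raise ValueError(f"site {chrom}:{pos}: {exc}") from exc
    return counts


# ---------------------------------------------------------------------------
# Reference signatures


@dataclass
class SignatureSet:
    """A 96 x S matrix of signature probabilities.

    ``matrix`` rows follow :data:`CHANNELS`; each column sums to 1.
    ``uv_members`` names the columns whose exposures are summed into the
    UV total (in the skin-signature nomenclature these are the two
    UV-caused signatures; in COSMIC terms, signature 7).
    """

    matrix: pd.DataFrame
    uv_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if list(self.matrix.index) != list(CHANNELS):
            raise ValueError("signature matrix rows must follow the SBS96 channel order")
        if (self.matrix.values < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-6)].index.tolist()
            raise ValueError(f"signature columns must sum to 1: {bad}")
        missing = set(self.uv_members) - set(self.matrix.columns)
        if missing:
            raise ValueError(f"uv_members not in signature set: {sorted(missing)}")

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)


def _profile_from_weights(weights: dict[str, float]) -> np.ndarray:
    v = np.zeros(96)
    for label, w in weights.items():
        v[_CHANNEL_INDEX[label]] = w
    return v / v.sum()


# UV-damage-like profile: C>T transitions concentrated at dipyrimidines,
# dominated by TCA/TCC/TCT contexts (COSMIC signature-7 style).
_UV_WEIGHTS = {
    "T[C>T]A": 0.22, "T[C>T]C": 0.20, "T[C>T]T": 0.18,
    "C[C>T]A": 0.07, "C[C>T]C": 0.08, "C[C>T]T": 0.07,
    "T[C>T]G": 0.04, "C[C>T]G": 0.03,
    "A[C>T]C": 0.02, "A[C>T]T": 0.02, "G[C>T]C": 0.02, "G[C>T]T": 0.02,
    "T[T>C]T": 0.015, "C[T>C]T": 0.015,
    "A[C>T]A": 0.005, "G[C>T]A": 0.005,
}

# Oxidative-damage-like profile: C>A dominated by ACA/GCA/GCT contexts
# (COSMIC signature-18 style, the 8-oxo-dG culture signature).
_CULTURE_WEIGHTS = {
    "A[C>A]A": 0.26, "G[C>A]A": 0.24, "G[C>A]T": 0.18,
    "T[C>A]T": 0.08, "A[C>A]T": 0.06, "C[C>A]A": 0.05,
    "T[C>A]A": 0.04, "G[C>A]C": 0.03, "A[C>A]C": 0.02,
    "T[C>A]C": 0.02, "C[C>A]T": 0.02,
}


def fallback_signatures() -> SignatureSet:
    """Packaged synthetic reference set: UV-like, oxidative and flat columns.

    These are stand-in profiles with the qualitative channel structure of
    the UV (signature-7-style) and oxidative-culture (signature-18-style)
    processes plus a flat background, intended for tests and synthetic
    pipelines; real analyses should load a published reference matrix.
    """
    matrix = pd.DataFrame(
        {
            "UVlike": _profile_from_weights(_UV_WEIGHTS),
            "Oxidative": _profile_from_weights(_CULTURE_WEIGHTS),
            "Flat": np.full(96, 1.0 / 96),
        },
        index=list(CHANNELS),
    )
    return SignatureSet(matrix=matrix, uv_members=("UVlike",))


# ---------------------------------------------------------------------------
# Exposure fitting


@dataclass
class ExposureEstimate:
    """Non-negative per-signature exposures, in mutation counts."""

    exposures: pd.Series
    stable: pd.Series
    residual_norm: float
    uv_total: float
    n_boot: int = 0
    bootstrap_sd: pd.Series | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"exposure": self.exposures, "stable": self.stable})


def _nnls_fit(catalog: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, float]:
    if catalog.sum() == 0:
        return np.zeros(matrix.shape[1]), 0.0
    coef, res = nnls(matrix, catalog.astype(float))
    return coef, float(res)


def fit_exposures(catalog: pd.Series, signatures: SignatureSet) -> ExposureEstimate:
    """Least-squares decomposition min ||catalog - M e||_2 subject to e >= 0."""
    _check_catalog(catalog)
    coef, res = _nnls_fit(catalog.to_numpy(), signatures.matrix.to_numpy())
    exposures = pd.Series(coef, index=signatures.names)
    stable = pd.Series(True, index=signatures.names)
    return ExposureEstimate(
        exposures=exposures,
        stable=stable,
        residual_norm=res,
        uv_total=float(exposures[list(signatures.uv_members)].sum()),
    )


def bootstrap_fit(
    catalog: pd.Series,
    signatures: SignatureSet,
    n_boot: int = 100,
    min_fraction: float = 0.05,
    stability_quantile: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> ExposureEstimate:
    """NNLS fit stabilised by multinomial bootstrap of the catalog.

    The catalog is resampled multinomially (preserving its total count)
    ``n_boot`` times and refit.  A signature is *stable* when its exposure
    exceeds ``min_fraction`` of the total in at least ``stability_quantile``
    of the bootstrap fits.  Unstable exposures are set to zero and the
    catalog is refit over the stable signatures only.
    """
    _check_catalog(catalog)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = signatures.names
    total = int(catalog.sum())
    if total == 0:
        zeros = pd.Series(0.0, index=names)
        return ExposureEstimate(
            exposures=zeros,
            stable=pd.Series(False, index=names),
            residual_norm=0.0,
            uv_total=0.0,
            n_boot=n_boot,
        )
    matrix = signatures.matrix.to_numpy()
    probs = catalog.to_numpy() / total
    hits = np.zeros(len(names))
    boot_exposures = np.empty((n_boot, len(names)))
    for b in range(n_boot):
        resampled = rng.multinomial(total, probs)
        coef, _ = _nnls_fit(resampled, matrix)
        boot_exposures[b] = coef
        hits += coef > min_fraction * total
    stable = pd.Series(hits / n_boot >= stability_quantile, index=names)
    if stable.any():
        coef_stable, res = _nnls_fit(
            catalog.to_numpy(), signatures.matrix.loc[:, stable].to_numpy()
        )
        exposures = pd.Series(0.0, index=names)
        exposures[stable[stable].index] = coef_stable
    else:
        exposures = pd.Series(0.0, index=names)
        res = float(np.linalg.norm(catalog.to_numpy()))
    return ExposureEstimate(
        exposures=exposures,
        stable=stable,
        residual_norm=res,
        uv_total=float(exposures[list(signatures.uv_members)].sum()),
        n_boot=n_boot,
        bootstrap_sd=pd.Series(boot_exposures.std(axis=0), index=names),
    )


def fit_partitions(
    calls: pd.DataFrame,
    signatures: SignatureSet,
    n_boot: int = 100,
    seed: int | None = None,
) -> tuple[ExposureEstimate, ExposureEstimate]:
    """Fit fibroblast-shared and private substitutions separately.

    ``calls`` must carry the boolean ``shared`` column set by the paired
    caller.  Partitions with no substitutions yield an all-zero,
    all-unstable estimate.
    """
    if "shared" not in calls.columns:
        raise ValueError("calls must carry a 'shared' column")
    rng = np.random.default_rng(seed)
    out = []
    for flag in (True, False):
        part = calls[calls["shared"] == flag]
        catalog = build_catalog(part, sample_id="shared" if flag else "private")
        out.append(bootstrap_fit(catalog, signatures, n_boot=n_boot, seed=rng))
    return out[0], out[1]


def cosine_similarity(catalog_a: pd.Series, catalog_b: pd.Series) -> float:
    """Cosine similarity between two 96-channel profiles, in [0, 1].

    Zero by convention when either vector is all-zero.
    """
    a = np.asarray(catalog_a, dtype=float)
    b = np.asarray(catalog_b, dtype=float)
    if a.shape != (96,) or b.shape != (96,):
        raise ValueError("catalogs must both have 96 channels")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def _check_catalog(catalog: pd.Series) -> None:
    if len(catalog) != 96:
        raise ValueError("catalog must have exactly 96 channels")
    if (np.asarray(catalog) < 0).any():
        raise ValueError("catalog counts must be non-negative")
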