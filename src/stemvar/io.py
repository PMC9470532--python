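"""Readers, writers, run configuration and the end-to-end pipeline.

The canonical interchange for paired read counts is a minimal two-sample
VCF (FORMAT ``AD`` carrying ref,alt depths per sample; germline and mask
annotations as INFO flags) mirrored by a TSV dialect for spreadsheet use.
All serialization is deterministic — fixed column order, ``%.6g`` floats —
so byte-identical reruns can be verified by digest.  ``run_pipeline``
chains simulate → call → catalog → fit → clonality → strand bias → stats
from a single-seed :class:`RunConfig` and writes a provenance block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import clonality, cohortstats, paircall, sigfit, strandbias, synth

__all__ = [
    "read_counts_table",
    "write_counts_tsv",
    "write_counts_vcf",
    "write_calls_tsv",
    "read_signatures_tsv",
    "write_signatures_tsv",
    "write_catalog_tsv",
    "read_catalog_tsv",
    "RunConfig",
    "run_pipeline",
    "PipelineError",
]

COUNT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "context",
    "parent_ref", "parent_alt", "derived_ref", "derived_alt",
    "germline_flag", "mask_low_mappability", "mask_cnv",
]
_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


# ---------------------------------------------------------------------------
# Paired counts: TSV and minimal VCF


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a paired counts table as TSV with the documented column order."""
    _validate_counts(counts)
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_counts_vcf(counts: pd.DataFrame, path: str | Path) -> None:
    """Write paired counts as a minimal VCF (two samples, AD fields only)."""
    _validate_counts(counts)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide context on the reference strand">',
        '##INFO=<ID=GERMLINE,Number=0,Type=Flag,Description="Population-frequency germline exclusion flag">',
        '##INFO=<ID=LOWMAP,Number=0,Type=Flag,Description="Low-mappability mask">',
        '##INFO=<ID=CNV,Number=0,Type=Flag,Description="Copy-number-alteration overlap mask">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depths for ref and alt alleles">',
    ]
    for chrom in pd.unique(counts["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPARENT\tDERIVED"
    )
    for row in counts.itertuples(index=False):
        info = [f"CTX={row.context}"] if row.context else []
        if row.germline_flag:
            info.append("GERMLINE")
        if row.mask_low_mappability:
            info.append("LOWMAP")
        if row.mask_cnv:
            info.append("CNV")
        lines.append(
            "\t".join(
                [
                    str(row.chrom), str(row.pos), ".", row.ref, row.alt, ".", ".",
                    ";".join(info) or ".",
                    "AD",
                    f"{row.parent_ref},{row.parent_alt}",
                    f"{row.derived_ref},{row.derived_alt}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read a paired counts table from TSV or minimal VCF (by extension).

    Records are validated (positive 1-based positions, non-negative
    counts); a malformed record raises with its line number.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_counts_vcf(path)
    return _read_counts_tsv(path)


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[COUNT_COLUMNS]
    df["context"] = df["context"].fillna("")
    _validate_counts(df, path=path, header_lines=1)
    return df


def _read_counts_vcf(path: Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if samples != ["PARENT", "DERIVED"]:
            raise ValueError(f"{path}: expected samples PARENT, DERIVED, got {samples}")
        for rec in vcf:
            p_ad = rec.samples["PARENT"]["AD"]
            d_ad = rec.samples["DERIVED"]["AD"]
            if p_ad is None or d_ad is None or None in p_ad or None in d_ad:
                raise ValueError(f"{path}: missing AD counts at {rec.chrom}:{rec.pos}")
            rows.append(
                (
                    rec.chrom, rec.pos, rec.ref, rec.alts[0],
                    rec.info.get("CTX", ""),
                    int(p_ad[0]), int(p_ad[1]), int(d_ad[0]), int(d_ad[1]),
                    bool(rec.info.get("GERMLINE", False)),
                    bool(rec.info.get("LOWMAP", False)),
                    bool(rec.info.get("CNV", False)),
                )
            )
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    _validate_counts(df, path=path)
    return df


def _validate_counts(
    df: pd.DataFrame, path: Path | None = None, header_lines: int = 0
) -> None:
    where = f"{path}: " if path else ""
    count_cols = ["parent_ref", "parent_alt", "derived_ref", "derived_alt"]
    for col in count_cols + ["pos"]:
        if df[col].isna().any():
            line = int(df[df[col].isna()].index[0]) + header_lines + 1
            raise ValueError(f"{where}missing {col} at line {line}")
    bad = (df[count_cols] < 0).any(axis=1)
    if bad.any():
        line = int(df[bad].index[0]) + header_lines + 1
        raise ValueError(f"{where}negative read count at line {line}")
    if (df["pos"] < 1).any():
        line = int(df[df["pos"] < 1].index[0]) + header_lines + 1
        raise ValueError(f"{where}non-positive position at line {line}")


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    cols = [
        c
        for c in [
            "chrom", "pos", "ref", "alt", "context", "p_value",
            "parent_vaf", "derived_vaf", "mut_class", "shared",
        ]
        if c in calls.columns
    ]
    calls[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Catalogs and signatures (channels as rows, samples/signatures as columns)


def write_catalog_tsv(catalogs: pd.DataFrame | pd.Series, path: str | Path) -> None:
    df = catalogs.to_frame() if isinstance(catalogs, pd.Series) else catalogs
    df = df.copy()
    df.index.name = "channel"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_catalog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="channel")
    if list(df.index) != list(sigfit.CHANNELS):
        raise ValueError(f"{path}: channel rows must follow the SBS96 order")
    return df


def write_signatures_tsv(signatures: sigfit.SignatureSet, path: str | Path) -> None:
    df = signatures.matrix.copy()
    df.index.name = "channel"
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_signatures_tsv(
    path: str | Path, uv_members: tuple[str, ...] = ()
) -> sigfit.SignatureSet:
    matrix = read_catalog_tsv(path)
    return sigfit.SignatureSet(matrix=matrix, uv_members=uv_members)


# ---------------------------------------------------------------------------
# Annotations (BED-like TSV; half-open [start, end), 1-based starts)


def write_annotations(tracks: synth.AnnotationTracks, genes_path, rt_path) -> None:
    tracks.gene_footprints.to_csv(genes_path, sep="\t", index=False)
    tracks.rt_bins.to_csv(rt_path, sep="\t", index=False)


def read_intervals(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Run configuration and pipeline


@dataclass
class RunConfig:
    """Top-level configuration of an end-to-end run.

    A single seed feeds every stage through deterministic splitting;
    unknown keys in a config file are rejected.
    """

    outdir: str = "stemvar_run"
    seed: int = 0
    sim: dict = field(default_factory=dict)
    caller: dict = field(default_factory=dict)
    n_boot: int = 50
    min_fraction: float = 0.05
    clonality_min_fraction: float = 0.10
    bandwidth: float | None = None
    signatures_path: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # where results land is not part of the run
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full synthetic-lineage analysis pipeline.

    Stages: simulate a parent population and one derived line per subclone,
    sample paired read counts, call somatic variants per line, build and
    fit SBS96 catalogs (shared/private partitions for line 0), deconvolve
    VAF clonality of parent and derived samples, tabulate strand bias, and
    summarise per-line statistics.  Returns a mapping of artifact names to
    file paths; reruns with the same config are byte-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "simulate"
    try:
        sim_cfg = synth.SimConfig(seed=config.seed, **config.sim)
        parent, tracks = synth.simulate_parent_population(sim_cfg)
        seeds = _stage_seeds(config.seed, 2 * sim_cfg.n_subclones + 2)
        write_annotations(tracks, outdir / "genes.tsv", outdir / "rt_bins.tsv")
        synth.truth_frame(parent).to_csv(outdir / "truth_parent.tsv", sep="\t", index=False)
        artifacts["genes"] = str(outdir / "genes.tsv")
        artifacts["rt_bins"] = str(outdir / "rt_bins.tsv")

        counts_by_line = {}
        for i in range(sim_cfg.n_subclones):
            derived = synth.simulate_derived_line(parent, sim_cfg, i, seed=seeds[2 * i])
            counts = synth.sample_read_counts(parent, derived, sim_cfg, seed=seeds[2 * i + 1])
            counts_by_line[f"line{i}"] = counts
            write_counts_tsv(counts, outdir / f"counts_line{i}.tsv")
            write_counts_vcf(counts, outdir / f"counts_line{i}.vcf")
            artifacts[f"counts_line{i}"] = str(outdir / f"counts_line{i}.tsv")

        stage = "call"
        caller_cfg = paircall.CallerConfig(**config.caller)
        calls_by_line = {}
        for name, counts in counts_by_line.items():
            result = paircall.call_variants(counts, caller_cfg)
            calls_by_line[name] = result.calls
            write_calls_tsv(result.calls, outdir / f"calls_{name}.tsv")
            artifacts[f"calls_{name}"] = str(outdir / f"calls_{name}.tsv")

        stage = "catalog"
        catalogs = pd.DataFrame(
            {
                name: sigfit.build_catalog(calls, sample_id=name)
                for name, calls in calls_by_line.items()
            }
        )
        write_catalog_tsv(catalogs, outdir / "catalogs.tsv")
        artifacts["catalogs"] = str(outdir / "catalogs.tsv")

        stage = "fit"
        if config.signatures_path is not None:
            if not Path(config.signatures_path).exists():
                raise FileNotFoundError(
                    f"signature file not found: {config.signatures_path}"
                )
            signatures = read_signatures_tsv(config.signatures_path)
        else:
            signatures = sigfit.fallback_signatures()
        fit_rows = {}
        for j, (name, calls) in enumerate(calls_by_line.items()):
            est = sigfit.bootstrap_fit(
                sigfit.build_catalog(calls, sample_id=name),
                signatures,
                n_boot=config.n_boot,
                min_fraction=config.min_fraction,
                seed=seeds[-1] + j,
            )
            fit_rows[name] = est.exposures
        exposures = pd.DataFrame(fit_rows)
        exposures.index.name = "signature"
        exposures.to_csv(outdir / "exposures.tsv", sep="\t", float_format=_FLOAT_FMT)
        artifacts["exposures"] = str(outdir / "exposures.tsv")

        shared_est, private_est = sigfit.fit_partitions(
            calls_by_line["line0"], signatures, n_boot=config.n_boot, seed=seeds[-2]
        )
        partition = pd.DataFrame(
            {"shared": shared_est.exposures, "private": private_est.exposures}
        )
        partition.index.name = "signature"
        partition.to_csv(outdir / "partition_exposures.tsv", sep="\t", float_format=_FLOAT_FMT)
        artifacts["partition_exposures"] = str(outdir / "partition_exposures.tsv")

        stage = "clonality"
        clon_rows = []
        for name, counts in counts_by_line.items():
            for sample, (ref_col, alt_col) in (
                ("parent", ("parent_ref", "parent_alt")),
                ("derived", ("derived_ref", "derived_alt")),
            ):
                if sample == "parent" and name != "line0":
                    continue  # one parent sample, shared by all lines
                calls = calls_by_line[name]
                vaf_col = f"{sample}_vaf"
                vafs = calls.loc[calls[vaf_col] > 0, vaf_col].to_numpy()
                label = "indeterminate"
                clusters: list = []
                if vafs.size >= clonality.MIN_MUTATIONS:
                    cs = clonality.find_clusters(
                        vafs,
                        min_fraction=config.clonality_min_fraction,
                        bandwidth=config.bandwidth,
                    )
                    label = clonality.classify_clonality(cs)
                    clusters = cs.clusters
                for c in clusters:
                    clon_rows.append(
                        (name, sample, c.mean_vaf, c.mutation_fraction,
                         c.subclone_fraction, label)
                    )
                if not clusters:
                    clon_rows.append((name, sample, np.nan, np.nan, np.nan, label))
        pd.DataFrame(
            clon_rows,
            columns=["line", "sample", "mean_vaf", "mutation_fraction",
                     "subclone_fraction", "classification"],
        ).to_csv(outdir / "clonality.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        artifacts["clonality"] = str(outdir / "clonality.tsv")

        stage = "strandbias"
        table = strandbias.tabulate(
            synth.truth_events(parent), tracks.gene_footprints, tracks.rt_bins
        )
        long = table.counts.rename("count").reset_index()
        long.to_csv(outdir / "strand_rt.tsv", sep="\t", index=False)
        artifacts["strand_rt"] = str(outdir / "strand_rt.tsv")

        stage = "stats"
        stat_rows = []
        names = list(calls_by_line)
        for name in names:
            calls = calls_by_line[name]
            stat_rows.append(
                (name, int((calls.get("mut_class") == "SNV").sum()),
                 int(calls["shared"].sum()) if "shared" in calls else 0)
            )
        pd.DataFrame(stat_rows, columns=["line", "n_snv", "n_shared"]).to_csv(
            outdir / "line_stats.tsv", sep="\t", index=False
        )
        artifacts["line_stats"] = str(outdir / "line_stats.tsv")
        if len(names) >= 2:
            a, b = names[0], names[1]
            # compare the mutations each line carries, not losses the
            # symmetric caller also flags
            carried = {
                n: calls_by_line[n][calls_by_line[n]["derived_vaf"] >= 0.2]
                for n in (a, b)
            }
            pair = cohortstats.pair_heterogeneity(
                carried[a], carried[b],
                sigfit.build_catalog(carried[a]), sigfit.build_catalog(carried[b]),
            )
            (outdir / "pair_comparison.json").write_text(
                json.dumps(pair._asdict(), indent=2) + "\n"
            )
            artifacts["pair_comparison"] = str(outdir / "pair_comparison.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package": "stemvar 0.1.0",
        "stages": list(artifacts),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    artifacts["provenance"] = str(outdir / "provenance.json")
    return artifacts
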