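"""Readers, writers, configuration, and the file-based pipeline run.

All genomic intervals are converted exactly once at the boundary:
GTF (1-based closed) and SNP positions (1-based) become 0-based
half-open / 0-based internally; BED-side formats pass through
unchanged.  Contact maps travel as per-chromosome triplet TSVs
(``bin_a_start  bin_b_start  count``) with the resolution in a header
comment.  Every pipeline run writes a manifest with a checksum per
output so that deterministic stages can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import pyranges as pr
import yaml

from . import pipeline as _pipeline
from .abc_model import ContactMap
from .annotation import TranscriptModel, promoter_table
from .quant import CountMatrix, junction_key
from .synthdata import SimBundle, SyntheticTruth

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- GTF

def read_gtf(path, max_error_rate: float = 0.1) -> list[TranscriptModel]:
    """Transcript models from a GTF (GENCODE dialect; exon features only).

    Exon rows missing ``transcript_id`` or ``gene_id`` are reported and
    skipped; the file is rejected when more than ``max_error_rate`` of
    exon rows are malformed.  Out-of-order exon lines are sorted.
    """
    df = pr.read_gtf(str(path)).df  # pyranges converts to 0-based half-open
    df = df[df["Feature"] == "exon"]
    bad = df["transcript_id"].isna() | (df["transcript_id"] == "") \
        | df["gene_id"].isna() | (df["gene_id"] == "")
    if bad.any():
        logger.error("%d exon rows missing gene_id/transcript_id", int(bad.sum()))
        if bad.mean() > max_error_rate:
            raise ValueError(
                f"{bad.mean():.0%} of exon rows malformed (limit {max_error_rate:.0%})"
            )
        df = df[~bad]
    out = []
    for tid, grp in df.groupby("transcript_id", sort=True):
        exons = tuple(sorted(zip(grp["Start"].astype(int), grp["End"].astype(int))))
        out.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=str(grp["gene_id"].iloc[0]),
                chrom=str(grp["Chromosome"].iloc[0]),
                strand=str(grp["Strand"].iloc[0]),
                exons=exons,
            )
        )
    return out


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    """Write exon features (1-based closed coordinates on disk)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda x: (x.gene_id, x.transcript_id)):
            for start, end in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\tpromlink\texon\t{start + 1}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ------------------------------------------------------------- tables

def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta.set_index("sample_id")


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.reset_index().to_csv(path, sep="\t", index=False)


def read_junction_counts(path, meta: pd.DataFrame) -> CountMatrix:
    """Junction TSV: chrom, donor, acceptor, strand, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    keys = [
        junction_key(c, int(d), int(a), s)
        for c, d, a, s in zip(df["chrom"], df["donor"], df["acceptor"], df["strand"])
    ]
    counts = df.drop(columns=["chrom", "donor", "acceptor", "strand"])
    counts.index = keys
    return CountMatrix(counts.loc[:, list(meta.index)], meta, "junction")


def write_junction_counts(cm: CountMatrix, path) -> None:
    rows = []
    for key in cm.counts.index:
        chrom, span, strand = key.rsplit(":", 2)
        donor, acceptor = span.split("-")
        rows.append((chrom, int(donor), int(acceptor), strand))
    head = pd.DataFrame(rows, columns=["chrom", "donor", "acceptor", "strand"])
    out = pd.concat([head.reset_index(drop=True), cm.counts.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_count_matrix(path, meta: pd.DataFrame, feature_kind: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.loc[:, list(meta.index)], meta, feature_kind)


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.counts.rename_axis("feature_id").to_csv(path, sep="\t")


def read_peaks(path) -> pd.DataFrame:
    """BED / narrowPeak: first 4 columns chrom, start, end, name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "ocr_id"]
    return df[["ocr_id", "chrom", "start", "end"]]


def write_peaks(peaks: pd.DataFrame, path) -> None:
    peaks[["chrom", "start", "end", "ocr_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_contact_map(path) -> ContactMap:
    """Triplet TSV with a ``# resolution=<bp> chrom=<name>`` header line."""
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise ValueError("contact file must start with a '# resolution=... chrom=...' line")
    fields = dict(kv.split("=") for kv in header.lstrip("# ").split())
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["bin_a_start", "bin_b_start", "count"])
    return ContactMap.from_triplets(df, int(fields["resolution"]), fields["chrom"])


def write_contact_map(cmap: ContactMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# resolution={cmap.resolution} chrom={cmap.chrom}\n")
        cmap.to_triplets().to_csv(fh, sep="\t", header=False, index=False)


def read_snps(path) -> pd.DataFrame:
    """SNP TSV: rsid, chrom, pos (1-based), pip."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_gene_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------ bundles

def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write a bundle as the standard-format files the CLI consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_gtf(bundle.transcripts, out / "annotation.gtf")
    write_sample_meta(bundle.meta, out / "samples.tsv")
    write_junction_counts(bundle.junction_counts, out / "junctions.tsv")
    write_count_matrix(bundle.gene_counts, out / "gene_counts.tsv")
    write_peaks(bundle.peaks, out / "peaks.bed")
    write_count_matrix(bundle.peak_counts, out / "peak_counts.tsv")
    for region, maps in bundle.contact_maps.items():
        for chrom, cmap in maps.items():
            write_contact_map(cmap, out / f"contacts_{region}_{chrom}.tsv")
    bundle.snps.to_csv(out / "snps.tsv", sep="\t", index=False)
    bundle.gene_scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    if bundle.truth is not None:
        tdir = out / "truth"
        tdir.mkdir(exist_ok=True)
        bundle.truth.major_promoters.to_csv(tdir / "major_promoters.tsv", sep="\t", index=False)
        bundle.truth.major_by_region.to_csv(tdir / "major_by_region.tsv", sep="\t", index=False)
        bundle.truth.switching.to_csv(tdir / "switching.tsv", sep="\t", index=False)
        bundle.truth.loops.to_csv(tdir / "loops.tsv", sep="\t", index=False)
        bundle.truth.causal.to_csv(tdir / "causal.tsv", sep="\t", index=False)


def read_bundle(indir) -> SimBundle:
    """Load a bundle directory written by :func:`write_bundle`."""
    from . import annotation as _ann

    d = Path(indir)
    transcripts = read_gtf(d / "annotation.gtf")
    promoters = _ann.classify_identifiability(
        _ann.build_promoters(transcripts), transcripts
    )
    meta = read_sample_meta(d / "samples.tsv")
    contact_maps: dict[str, dict[str, ContactMap]] = {}
    for f in sorted(d.glob("contacts_*.tsv")):
        _, region, chrom = f.stem.split("_", 2)
        contact_maps.setdefault(region, {})[chrom] = read_contact_map(f)
    truth = None
    tdir = d / "truth"
    if tdir.is_dir():
        truth = SyntheticTruth(
            major_promoters=pd.read_csv(tdir / "major_promoters.tsv", sep="\t"),
            major_by_region=pd.read_csv(tdir / "major_by_region.tsv", sep="\t"),
            switching=pd.read_csv(tdir / "switching.tsv", sep="\t"),
            loops=pd.read_csv(tdir / "loops.tsv", sep="\t"),
            causal=pd.read_csv(tdir / "causal.tsv", sep="\t"),
            inflated_genes=[], internal_promoters=[],
        )
    return SimBundle(
        transcripts=transcripts,
        promoters=promoters,
        meta=meta,
        junction_counts=read_junction_counts(d / "junctions.tsv", meta),
        gene_counts=read_count_matrix(d / "gene_counts.tsv", meta, "gene"),
        peaks=read_peaks(d / "peaks.bed"),
        peak_counts=read_count_matrix(d / "peak_counts.tsv", meta, "ocr"),
        contact_maps=contact_maps,
        snps=read_snps(d / "snps.tsv"),
        gene_scores=read_gene_scores(d / "scores.tsv"),
        truth=truth,
    )


# ------------------------------------------------------------- config

KNOWN_CONFIG_KEYS = {
    "input_dir", "output_dir", "seed", "log_level",
    "fdr_cut", "gene_null_p", "abc_threshold", "abc_window_bp", "gamma",
    "pip_min", "promoter_window_bp", "group_col", "compute_pi1", "include_ocr_de",
}


def load_run_config(path) -> dict:
    """YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """File-based end-to-end run; writes outputs and a checksum manifest.

    ``config`` keys: ``input_dir`` (a bundle directory), ``output_dir``,
    and any :class:`~promlink.pipeline.PipelineParams` field.  Returns
    the manifest (relative path -> sha256).
    """
    indir, outdir = Path(config["input_dir"]), Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    param_keys = {
        k: v for k, v in config.items()
        if k in _pipeline.PipelineParams.__dataclass_fields__
    }
    params = _pipeline.PipelineParams(**param_keys)
    try:
        stage = "read"
        bundle = read_bundle(indir)
        stage = "abc"
        missing = [
            r for r in sorted(bundle.meta["region"].astype(str).unique())
            if r not in bundle.contact_maps
        ]
        if missing:
            raise ValueError(f"missing contact maps for regions {missing}")
        stage = "pipeline"
        outputs = _pipeline.run_bundle(bundle, params)
    except Exception as err:
        (outdir / "failed").write_text(f"stage '{stage}' failed: {err}\n")
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err
    failed_marker = outdir / "failed"
    if failed_marker.exists():
        failed_marker.unlink()

    promoter_table(outputs["promoters"]).to_csv(
        outdir / "promoters.tsv", sep="\t", index=False
    )
    for name in ("iso_de", "gene_de", "iso_specific", "specific_genes",
                 "specific_promoters", "major_promoters", "links",
                 "assignments", "closest_gene"):
        df = outputs[name]
        if df is not None:
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    if outputs["pi1"] is not None:
        outputs["pi1"].rename_axis("region").to_csv(outdir / "pi1.tsv", sep="\t")
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    manifest = {
        f.name: _sha256(f)
        for f in sorted(outdir.glob("*.tsv"))
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
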