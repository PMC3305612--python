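"""FASTA/metadata ingestion, the minimum-length filter, and tabular output.

The ingestion contract: every FASTA record is analyzed independently;
records whose length is not strictly greater than ``min_length`` (default
10,000 bp — short sequences give unstable 256-cell spectra) are excluded
and counted in the run log.  Metadata is an optional TSV with columns
``id  class  phylum  domain  species``; sequences without a metadata row
are assigned class "other".

All floating-point table output is printed with 6 significant digits.
Window TSVs carry both the raw per-window D_KL and its difference from the
chromosome mean; flagged intervals are written as BED3 (0-based, half-open).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .signature import EntropyResult, SequenceRecord, analyze_sequence
from .windows import WindowProfile

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "ingest",
    "cohort_table",
    "write_entropy_tsv",
    "read_entropy_tsv",
    "write_windows_tsv",
    "write_bed",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"
ENTROPY_COLUMNS = ["id", "length", "valid_windows", "at_content",
                   "gc_content", "dkl", "douv"]
METADATA_COLUMNS = ["id", "class", "phylum", "domain", "species"]


@dataclass
class RunConfig:
    """Settings of one pipeline run."""

    fasta_paths: list[str] = field(default_factory=list)
    metadata_path: str | None = None
    out_dir: str = "."
    min_length: int = 10_000
    window_size: int = 5000
    flag_sd: float = 2.0
    log_base: float | None = None  # None -> natural log (nats)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 4:
            raise ValueError("min_length must be >= 4")
        if self.window_size < 1000:
            raise ValueError("window_size must be >= 1000")


def read_fasta(paths) -> list[SequenceRecord]:
    """Read one or more multi-FASTA files into sequence records.

    Duplicate ids across all inputs are an error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(SequenceRecord(id=rec.id, residues=str(rec.seq)))
    if not records:
        raise ValueError(f"no records in {', '.join(map(str, paths))}")
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 80) -> None:
    bio = [BioSeqRecord(Seq(r.residues), id=r.id, description="")
           for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in meta.columns:
        raise ValueError(f"metadata {path} lacks an 'id' column")
    if meta["id"].duplicated().any():
        dup = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate metadata ids: {dup}")
    return meta


def ingest(fasta_paths, metadata_path=None, min_length: int = 10_000,
           ) -> tuple[list[SequenceRecord], pd.DataFrame, dict[str, int]]:
    """Read sequences, attach metadata, apply the strict length filter.

    Only sequences strictly longer than ``min_length`` survive.  Metadata
    ids must be a subset of the FASTA ids; sequences without metadata get
    class "other".  Returns (records, metadata, counts).
    """
    records = read_fasta(fasta_paths)
    ids = {r.id for r in records}
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        unknown = sorted(set(meta["id"]) - ids)
        if unknown:
            raise ValueError(f"metadata ids not present in FASTA: {unknown}")
    else:
        meta = pd.DataFrame(columns=METADATA_COLUMNS)

    kept = [r for r in records if r.length > min_length]
    counts = {"read": len(records), "filtered_short": len(records) - len(kept),
              "analyzed": len(kept)}
    logger.info("ingest: %(read)d read, %(filtered_short)d below length "
                "filter, %(analyzed)d analyzed", counts)

    by_id = dict(zip(meta["id"], meta.to_dict("records"))) if len(meta) else {}
    for rec in kept:
        row = by_id.get(rec.id)
        if row is None:
            logger.info("no metadata for %s; class set to 'other'", rec.id)
            rec.class_label = "other"
        else:
            rec.class_label = row.get("class") or "other"
            rec.phylum = row.get("phylum")
            rec.domain_label = row.get("domain")
    return kept, meta, counts


def results_frame(results: list[EntropyResult]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    return df[ENTROPY_COLUMNS]


def cohort_table(results: list[EntropyResult],
                 metadata: pd.DataFrame | None = None,
                 dedupe_species: bool = False) -> pd.DataFrame:
    """Join per-sequence entropy results with metadata into the cohort table.

    With ``dedupe_species=True`` only the first occurrence of each species
    is kept (for phylum-level models, which expect one row per species).
    """
    df = results_frame(results)
    if df["id"].duplicated().any():
        raise ValueError("duplicate result ids")
    if metadata is not None and len(metadata):
        df = df.merge(metadata, on="id", how="left")
    for col in ("class", "phylum", "domain", "species"):
        if col not in df.columns:
            df[col] = None
    df["class"] = df["class"].fillna("other")
    if dedupe_species:
        df = df.drop_duplicates(subset="species", keep="first")
    return df.reset_index(drop=True)


def write_entropy_tsv(results: list[EntropyResult], path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False,
                                  float_format=FLOAT_FORMAT)


def read_entropy_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_windows_tsv(profiles: list[WindowProfile], path) -> None:
    rows = []
    for prof in profiles:
        mean = prof.mean_window_dkl
        for start, dkl in zip(prof.window_starts, prof.window_dkls):
            rows.append({"id": prof.id, "start": int(start),
                         "end": int(start) + prof.window_size,
                         "dkl": dkl, "dkl_minus_mean": dkl - mean})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FORMAT)


def write_bed(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    """Write flagged intervals per sequence id as BED3."""
    with open(path, "w") as fh:
        for seq_id, ivals in intervals.items():
            for start, end in ivals:
                fh.write(f"{seq_id}\t{start}\t{end}\n")


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Ingest, analyze, and write the per-sequence entropy table.

    Returns a bundle with the records, results, cohort table and run-log
    counts.  Stage failures propagate with the stage named in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        records, meta, counts = ingest(config.fasta_paths,
                                       config.metadata_path,
                                       config.min_length)
    except Exception:
        logger.error("pipeline stage 'ingest' failed")
        raise
    try:
        results = [analyze_sequence(r, log_base=config.log_base)
                   for r in records]
    except Exception:
        logger.error("pipeline stage 'analyze' failed")
        raise
    write_entropy_tsv(results, out / "entropy.tsv")
    table = cohort_table(results, meta if len(meta) else None)
    with open(out / "run_log.json", "w") as fh:
        json.dump({"counts": counts, "seed": config.seed,
                   "min_length": config.min_length,
                   "window_size": config.window_size}, fh, indent=2)
    return {"records": records, "results": results, "table": table,
            "counts": counts}
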