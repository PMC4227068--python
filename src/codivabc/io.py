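"""File formats: FASTA alignments, sample sheets, prior/posterior tables.

Observed data arrive as one FASTA per (pair, locus) plus a tab-separated
sample sheet binding files to pairs and loci.  Sequence IDs follow
``<pair>__pop{1|2}__<index>``.  IUPAC ambiguity codes and gaps are read
as missing and excluded pairwise in the statistics.

Prior tables and retained posteriors are headered TSV (gzip accepted by
extension); each table travels with a JSON sidecar recording the schema
version, column order, and — for posteriors — the standardization
constants, observed vector, and realized tolerance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .abc import SCHEMA_VERSION, PosteriorEstimate, PriorTable
from .mutate import NUCLEOTIDES, Alignment

__all__ = [
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_sample_sheet",
    "write_observed_stats",
    "read_observed_stats",
    "write_prior_table",
    "read_prior_table",
    "write_posterior",
    "read_posterior",
    "file_sha256",
    "SchemaError",
]


class SchemaError(ValueError):
    """A table or sidecar does not match the expected schema."""


_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}


def _encode_seq(s: str) -> np.ndarray:
    out = np.full(len(s), -1, dtype=np.int8)
    for i, ch in enumerate(s.upper()):
        out[i] = _CODE.get(ch, -1)
    return out


def read_alignment_fasta(path, *, pair_label: str,
                         locus_id: str) -> Alignment:
    """Read one per-locus FASTA; population membership comes from the
    ``<pair>__pop{1|2}__<index>`` sequence IDs."""
    from Bio import SeqIO

    seqs, pops = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("__")
        if len(fields) != 3 or fields[1] not in ("pop1", "pop2"):
            raise SchemaError(f"sequence ID {rec.id!r} in {path} is not "
                              "of the form <pair>__pop{1|2}__<index>")
        if fields[0] != pair_label:
            raise SchemaError(f"sequence {rec.id!r} does not belong to "
                              f"pair {pair_label!r}")
        seqs.append(_encode_seq(str(rec.seq)))
        pops.append(0 if fields[1] == "pop1" else 1)
    if not seqs:
        raise SchemaError(f"no sequences in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise SchemaError(f"unequal sequence lengths in {path}")
    return Alignment(np.vstack(seqs), np.asarray(pops, dtype=np.int8),
                     pair_label, locus_id)


def write_alignment_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        counters = [0, 0]
        for row, pop in zip(aln.seqs, aln.pops):
            counters[pop] += 1
            seq = "".join(NUCLEOTIDES[c] if c >= 0 else "N" for c in row)
            fh.write(f">{aln.pair_label}__pop{pop + 1}__"
                     f"{counters[pop]}\n{seq}\n")


def read_sample_sheet(path) -> list[Alignment]:
    """Read a sample sheet (columns: pair, locus, fasta) and the FASTA
    files it points to.  Paths are relative to the sheet."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pair", "locus", "fasta"}
    if not required.issubset(sheet.columns):
        raise SchemaError(f"sample sheet {path} must have columns "
                          f"{sorted(required)}; has "
                          f"{sorted(sheet.columns)}")
    base = Path(path).parent
    alignments = []
    for _, row in sheet.iterrows():
        fasta = Path(row["fasta"])
        if not fasta.is_absolute():
            fasta = base / fasta
        alignments.append(read_alignment_fasta(
            fasta, pair_label=row["pair"], locus_id=row["locus"]))
    return alignments


def write_observed_stats(sv, path) -> None:
    """Observed summary vector as TSV, one row per block."""
    from .sumstats import STAT_NAMES

    df = pd.DataFrame(sv.values, columns=list(STAT_NAMES))
    df.insert(0, "block", np.arange(sv.n_blocks))
    df["pi_b"] = sv.pi_b
    if sv.labels is not None:
        df.insert(1, "pair", list(sv.labels))
    df.attrs["ordering_mode"] = sv.ordering_mode
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION} "
                 f"ordering_mode={sv.ordering_mode}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_observed_stats(path):
    from .sumstats import STAT_NAMES, SummaryVector

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# schema_version="):
            raise SchemaError(f"{path} lacks the schema header line")
        meta = dict(item.split("=", 1)
                    for item in header[2:].strip().split())
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in STAT_NAMES if c not in df.columns]
    if missing or "pi_b" not in df.columns:
        raise SchemaError(f"{path} is missing columns {missing}")
    labels = tuple(df["pair"]) if "pair" in df.columns else None
    return SummaryVector(df[list(STAT_NAMES)].to_numpy(dtype=float),
                         df["pi_b"].to_numpy(dtype=float),
                         meta["ordering_mode"], labels=labels)


def _sidecar(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".tsv.gz", ".tsv"):
        if name.endswith(suffix):
            return p.with_name(name[:-len(suffix)] + ".schema.json")
    return p.with_name(name + ".schema.json")


def write_prior_table(table: PriorTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "prior_table",
        "n": table.n,
        "seed": table.seed,
        "columns": list(table.df.columns),
        "summary_columns": table.summary_columns,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_prior_table(path) -> PriorTable:
    df = pd.read_csv(path, sep="\t")
    sidecar = _sidecar(path)
    seed = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(f"{sidecar} has schema_version "
                              f"{meta.get('schema_version')}; expected "
                              f"{SCHEMA_VERSION}")
        if meta.get("columns") != list(df.columns):
            raise SchemaError(f"column schema of {path} does not match "
                              "its sidecar")
        seed = meta.get("seed")
    return PriorTable(df, seed=seed)


def write_posterior(post: PosteriorEstimate, prefix) -> None:
    """Write a posterior estimate as ``<prefix>.tsv`` (retained rows plus
    distance; adjusted values as ``adj_`` columns when present) and
    ``<prefix>.json`` (tolerance, standardization constants, pmfs)."""
    from .abc import summarize_posterior

    prefix = Path(prefix)
    df = post.retained.copy()
    df["_distance"] = post.distances
    df["_prior_row"] = post.indices
    if post.adjusted is not None:
        for col in post.adjusted.columns:
            if not col.startswith("s_") and \
                    pd.api.types.is_numeric_dtype(post.adjusted[col]) and \
                    not (post.adjusted[col] == df[col]).all():
                df[f"adj_{col}"] = post.adjusted[col]
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "posterior",
        "epsilon": post.epsilon,
        "n_retained": post.n_retained,
        "summary_columns": list(post.summary_columns),
        "means": post.means.tolist(),
        "sds": post.sds.tolist(),
        "observed": post.observed.tolist(),
        "observed_std": post.observed_std.tolist(),
        "summary": summarize_posterior(post),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_posterior(prefix) -> PosteriorEstimate:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION or \
            meta.get("kind") != "posterior":
        raise SchemaError(f"{prefix}.json is not a posterior sidecar of "
                          f"schema version {SCHEMA_VERSION}")
    adj_cols = [c for c in df.columns if c.startswith("adj_")]
    distances = df.pop("_distance").to_numpy(dtype=float)
    indices = df.pop("_prior_row").to_numpy(dtype=int)
    adjusted = None
    if adj_cols:
        adjusted = df.drop(columns=adj_cols).copy()
        for c in adj_cols:
            adjusted[c[4:]] = df[c]
        df = df.drop(columns=adj_cols)
    return PosteriorEstimate(
        retained=df,
        indices=indices,
        distances=distances,
        epsilon=float(meta["epsilon"]),
        observed=np.asarray(meta["observed"], dtype=float),
        observed_std=np.asarray(meta["observed_std"], dtype=float),
        means=np.asarray(meta["means"], dtype=float),
        sds=np.asarray(meta["sds"], dtype=float),
        summary_columns=tuple(meta["summary_columns"]),
        adjusted=adjusted,
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
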