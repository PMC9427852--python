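"""Readers and writers for the table/sequence formats shared across the pipeline.

Conventions used throughout the package:

* count and TPM matrices are ``pandas.DataFrame`` objects, genes as rows
  (index = ``gene_id``), samples as columns;
* the sample sheet is a ``DataFrame`` with columns ``sample_id``, ``layer``
  (``transcriptome`` | ``translatome``), ``stage``, ``species``, ``replicate``;
* gene annotation is a ``DataFrame`` indexed by ``gene_id`` with columns
  ``gene_name``, ``biotype``, ``effective_length``;
* all sequence coordinates are 0-based, half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

LAYERS = ("transcriptome", "translatome")

ANNOTATION_COLUMNS = ["gene_name", "biotype", "effective_length"]
SAMPLE_SHEET_COLUMNS = ["sample_id", "layer", "stage", "species", "replicate"]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix from TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene_id in count matrix: {dup!r}")
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative values")
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    bad = set(df["layer"]) - set(LAYERS)
    if bad:
        raise ValueError(f"unknown layer values in sample sheet: {sorted(bad)}")
    if df.duplicated(subset=["sample_id", "layer"]).any():
        raise ValueError("(sample_id, layer) pairs in sample sheet must be unique")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (gene_id, gene_name, biotype, effective_length)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    missing = [c for c in ["gene_id", *ANNOTATION_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene_id in annotation: {dup!r}")
    if (df["effective_length"] < 1).any():
        bad = df.index[df["effective_length"] < 1][0]
        raise ValueError(f"effective_length < 1 for gene {bad!r}")
    return df


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def annotation_from_gtf(path: str | Path) -> pd.DataFrame:
    """Derive a gene annotation table from a GTF file.

    The effective length is the union-exon length per gene (merged exon
    intervals). Attribute keys ``gene_id``, ``gene_name`` and
    ``gene_biotype``/``gene_type`` are accepted.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"GTF exon line without gene_id: {line[:80]!r}")
            start, end = int(fields[3]), int(fields[4])  # GTF is 1-based inclusive
            exons.setdefault(gid, []).append((start - 1, end))
            if gid not in meta:
                meta[gid] = {
                    "gene_name": attrs.get("gene_name", gid),
                    "biotype": attrs.get("gene_biotype", attrs.get("gene_type", "other")),
                }
    rows = []
    for gid, ivs in exons.items():
        ivs.sort()
        length = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                length += cur_e - cur_s
                cur_s, cur_e = s, e
        length += cur_e - cur_s
        rows.append((gid, meta[gid]["gene_name"], meta[gid]["biotype"], length))
    df = pd.DataFrame(rows, columns=["gene_id", *ANNOTATION_COLUMNS]).set_index("gene_id")
    return df


def read_utr_fasta(path: str | Path) -> dict[str, str]:
    """Read 3'-UTR sequences; headers are gene ids, sequences uppercased, T -> U."""
    utrs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in utrs:
            raise ValueError(f"duplicate sequence id in FASTA: {rec.id!r}")
        utrs[rec.id] = str(rec.seq).upper().replace("T", "U")
    return utrs


def write_utr_fasta(utrs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, seq in utrs.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, provenance: str | None = None,
                index: bool = True) -> None:
    """Write a TSV with an optional leading '#' provenance line."""
    with open(path, "w") as fh:
        if provenance is not None:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=index)
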