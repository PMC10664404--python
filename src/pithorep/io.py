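"""Readers and writers for the external formats the analyses consume.

FASTA genomes/proteomes (via Biopython), BED6 intervals, minimal GFF3
gene tables, OrthoFinder N0-style hierarchical orthologous group (HOG)
tables, 12-column tabular alignment files, per-position IPD-ratio
tracks, and Newick species trees.

Coordinate conventions: BED and everything in memory are 0-based
half-open; GFF3 and tabular alignment files are 1-based inclusive and
are converted on the way in/out.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import CircularGenome

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, circular: bool = True) -> list[CircularGenome]:
    """Read a FASTA file into :class:`CircularGenome` records."""
    return [
        CircularGenome(id=rec.id, seq=str(rec.seq).upper(), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str] | CircularGenome], path) -> None:
    """Write (id, seq) pairs or genomes to FASTA."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, CircularGenome):
            seqrecords.append(SeqRecord(Seq(rec.seq), id=rec.id, description=""))
        else:
            name, seq = rec
            seqrecords.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED6

def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file (tab-separated, no header) into a DataFrame."""
    df = pd.read_csv(
        str(path), sep="\t", header=None, comment="#",
        names=BED_COLUMNS, dtype={"chrom": str, "name": str, "strand": str},
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a DataFrame holding at least chrom/start/end to BED6."""
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[BED_COLUMNS].to_csv(str(path), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3 (minimal: ID, coordinates, strand, type)

def read_gff3(path, feature_types: Sequence[str] | None = ("gene", "CDS")) -> pd.DataFrame:
    """Read gene features from a GFF3 file.

    Returns a DataFrame with 0-based half-open ``start``/``end``,
    ``strand``, ``type`` and the ``ID`` attribute as ``gene_id``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if feature_types is not None and ftype not in feature_types:
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            rows.append(
                {
                    "genome": seqid,
                    "gene_id": attr_map.get("ID", f"{seqid}:{start}-{end}"),
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "type": ftype,
                }
            )
    return pd.DataFrame(rows, columns=["genome", "gene_id", "start", "end", "strand", "type"])


def write_gff3(genes: pd.DataFrame, path, source: str = "pithorep") -> None:
    """Write a gene table (0-based half-open) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(g["genome"]),
                        source,
                        str(g.get("type", "gene")),
                        str(int(g["start"]) + 1),
                        str(int(g["end"])),
                        ".",
                        str(g.get("strand", "+")),
                        ".",
                        f"ID={g['gene_id']}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# HOG tables (OrthoFinder N0-style)

def read_hog_tsv(path, genome_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read an N0-style HOG table into a genome x HOG gene-count frame.

    The input has one row per HOG, a ``HOG`` id column, and one column
    per genome holding comma-separated gene identifiers (empty when the
    genome lacks the HOG).  Returns a DataFrame indexed by genome with
    one integer column per HOG (gene-copy counts).
    """
    raw = pd.read_csv(str(path), sep="\t", dtype=str).fillna("")
    hog_col = "HOG" if "HOG" in raw.columns else raw.columns[0]
    meta = {hog_col, "OG", "Gene Tree Parent Clade"}
    if genome_columns is None:
        genome_columns = [c for c in raw.columns if c not in meta]
    mat = np.zeros((len(genome_columns), len(raw)), dtype=int)
    for j, col in enumerate(genome_columns):
        mat[j] = [
            0 if cell.strip() == "" else sum(1 for g in cell.split(",") if g.strip())
            for cell in raw[col]
        ]
    return pd.DataFrame(mat, index=list(genome_columns), columns=list(raw[hog_col]))


def write_hog_tsv(counts: pd.DataFrame, path) -> None:
    """Write a genome x HOG count frame back to N0-style TSV.

    Gene ids are synthesized as ``<genome>_<hog>_<i>`` since counts do
    not retain the original identifiers.
    """
    rows = []
    for hog in counts.columns:
        row = {"HOG": hog}
        for genome in counts.index:
            n = int(counts.loc[genome, hog])
            row[genome] = ", ".join(f"{genome}_{hog}_{i}" for i in range(n))
        rows.append(row)
    pd.DataFrame(rows).to_csv(str(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tabular alignment files (12-column, BLAST outfmt-6 compatible)

TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_tabular_alignments(path) -> pd.DataFrame:
    """Parse a 12-column tabular alignment file (1-based inclusive).

    Coordinates are converted to 0-based half-open; hits on the minus
    strand (sstart > send in the file) get ``strand`` "-" with
    normalized subject coordinates.
    """
    try:
        df = pd.read_csv(str(path), sep="\t", header=None, names=TABULAR_COLUMNS, comment="#")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed tabular alignment file {path}: {exc}") from exc
    for lineno, row in enumerate(df.itertuples(index=False), 1):
        for fieldname in ("qstart", "qend", "sstart", "send"):
            val = getattr(row, fieldname)
            if not float(val).is_integer():
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate {fieldname}={val}")
    strand = np.where(df["sstart"] <= df["send"], "+", "-")
    s_lo = np.minimum(df["sstart"], df["send"]).astype(int)
    s_hi = np.maximum(df["sstart"], df["send"]).astype(int)
    out = pd.DataFrame(
        {
            "q_start": df["qstart"].astype(int) - 1,
            "q_end": df["qend"].astype(int),
            "s_start": s_lo - 1,
            "s_end": s_hi,
            "strand": strand,
            "identity_pct": df["pident"].astype(float),
            "evalue": df["evalue"].astype(float),
            "bitscore": df["bitscore"].astype(float),
        }
    )
    return out


# ---------------------------------------------------------------------------
# IPD-ratio tracks

def read_ipd_tsv(path) -> pd.DataFrame:
    """Read a per-position IPD-ratio track.

    Expected columns: ``genome_id``, ``position`` (0-based nt) and
    ``ipd_ratio``; a header line is required.
    """
    df = pd.read_csv(str(path), sep="\t")
    required = {"genome_id", "position", "ipd_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"IPD track {path} missing columns {sorted(missing)}")
    if (df["ipd_ratio"] < 0).any():
        raise ValueError("IPD ratios must be nonnegative")
    if df.duplicated(["genome_id", "position"]).any():
        raise ValueError("IPD track has duplicate positions")
    return df


def write_ipd_tsv(df: pd.DataFrame, path) -> None:
    df[["genome_id", "position", "ipd_ratio"]].to_csv(str(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick species trees

def read_tree(path_or_string):
    """Read a rooted Newick tree (file path or literal string)."""
    text = str(path_or_string)
    if text.lstrip().startswith("(") and text.rstrip().endswith(";"):
        handle = _io.StringIO(text)
        return Phylo.read(handle, "newick")
    return Phylo.read(text, "newick")
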