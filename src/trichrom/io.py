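"""Readers and writers for the on-disk interchange formats.

Plain-text TSV is canonical throughout: the pairs-like contact table, BED4/
BED6 intervals, bedGraph tracks, BEDPE loop lists, and COO (bin_i, bin_j,
count) matrices with a companion bin BED.  All coordinates on disk are
0-based half-open; :func:`to_one_based` is the single conversion point for
1-based display.  FASTA goes through Bio.SeqIO.

The pairs format, one record per line, tab-separated, ``#`` header lines::

    readID chrom1 pos1 strand1 frag1 chrom2 pos2 strand2 frag2 \
    sonication_end allele copies

with ``.`` for missing values.  Reads are strict: a malformed line raises an
error naming the line number; writes are canonical so read→write round trips
are byte-identical.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contacts import PAIRS_COLUMNS, ContactTable
from .digest import FragmentMap
from .hic import ContactMatrix
from .simulate import HotspotSpec, LoopSpec, SimulationSpec

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "write_pairs",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_bedpe",
    "write_bedpe",
    "read_matrix",
    "write_matrix",
    "write_fragment_map",
    "read_config",
    "file_checksum",
    "to_one_based",
]


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive display."""
    return start + 1, end


def file_checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ── FASTA ────────────────────────────────────────────────────────────────

def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA (wrapped or unwrapped) as {name: sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ── pairs-like contact table ─────────────────────────────────────────────

def _fmt_int_or_dot(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "."
    return str(int(v))


def read_pairs(path: str | Path) -> ContactTable:
    header_lines: list[str] = []
    rows: list[tuple] = []
    meta: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header_lines.append(line)
                if "=" in line:
                    k, _, v = line[1:].partition("=")
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        parts[0],
                        parts[1], int(parts[2]), parts[3], int(parts[4]),
                        parts[5], int(parts[6]), parts[7], int(parts[8]),
                        float(parts[9]) if parts[9] != "." else math.nan,
                        parts[10],
                        int(parts[11]),
                    )
                )
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from None
    df = pd.DataFrame(rows, columns=PAIRS_COLUMNS)
    df["viewpoint_id"] = meta.get("viewpoint_id", ".")
    meta["header_lines"] = header_lines
    return ContactTable(df, meta)


def write_pairs(table: ContactTable, path: str | Path) -> None:
    meta = table.meta
    header_lines = meta.get("header_lines")
    if header_lines is None:
        header_lines = ["## pairs-like TSV (trichrom)"]
        vp = table.df["viewpoint_id"]
        distinct = sorted(set(vp) - {"."})
        if len(distinct) == 1:
            header_lines.append(f"#viewpoint_id={distinct[0]}")
        for k in ("mode", "source", "enzymes", "fragment_map"):
            if k in meta:
                header_lines.append(f"#{k}={meta[k]}")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        for r in table.df.itertuples(index=False):
            fh.write(
                "\t".join(
                    (
                        str(r.read_id),
                        str(r.chrom1), str(int(r.pos1)), str(r.strand1),
                        str(int(r.frag1)),
                        str(r.chrom2), str(int(r.pos2)), str(r.strand2),
                        str(int(r.frag2)),
                        _fmt_int_or_dot(r.sonication_end),
                        str(r.allele),
                        str(int(r.copies)),
                    )
                )
                + "\n"
            )


# ── BED / bedGraph / BEDPE ───────────────────────────────────────────────

def _parse_interval(parts, lineno, path):
    start, end = int(parts[1]), int(parts[2])
    if end <= start:
        raise ValueError(f"{path}: line {lineno}: end <= start")
    return parts[0], start, end


def read_bed(path: str | Path) -> list[tuple]:
    """BED records as tuples (chrom, start, end, *extra columns as strings)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom, start, end = _parse_interval(parts, lineno, path)
            out.append((chrom, start, end, *parts[3:]))
    return out


def write_bed(records: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(v) for v in rec) + "\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start, end = _parse_interval(parts, lineno, path)
            rows.append((chrom, start, end, float(parts[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(
    df: pd.DataFrame, path: str | Path, precision: int = 6
) -> None:
    """Write (chrom, start, end, value) rows; adjacent equal values are kept
    un-merged so the binning stays explicit."""
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t"
                f"{round(float(r.value), precision):g}\n"
            )


def read_bedpe(path: str | Path) -> list[tuple]:
    """BEDPE loop records (chrom1, s1, e1, chrom2, s2, e2, *extra)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: fewer than 6 columns")
            c1, s1, e1 = _parse_interval(parts[0:3], lineno, path)
            c2, s2, e2 = _parse_interval(parts[3:6], lineno, path)
            out.append((c1, s1, e1, c2, s2, e2, *parts[6:]))
    return out


def write_bedpe(records: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(v) for v in rec) + "\n")


# ── COO matrix TSV + companion bin BED ───────────────────────────────────

def write_matrix(matrix: ContactMatrix, prefix: str | Path) -> None:
    prefix = str(prefix)
    with open(prefix + ".coo.tsv", "w") as fh:
        fh.write(f"#chrom={matrix.chrom}\n#resolution={matrix.resolution}\n")
        for i, j, c in zip(matrix.bin_i, matrix.bin_j, matrix.count):
            fh.write(f"{i}\t{j}\t{c}\n")
    r = matrix.resolution
    write_bed(
        ((matrix.chrom, b * r, (b + 1) * r, b) for b in range(matrix.n_bins)),
        prefix + ".bins.bed",
    )


def read_matrix(prefix: str | Path) -> ContactMatrix:
    prefix = str(prefix)
    meta: dict = {}
    ii, jj, cc = [], [], []
    with open(prefix + ".coo.tsv") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k] = v
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 columns")
            ii.append(int(parts[0]))
            jj.append(int(parts[1]))
            cc.append(int(parts[2]))
    bins = read_bed(prefix + ".bins.bed")
    return ContactMatrix(
        meta.get("chrom", bins[0][0] if bins else "?"),
        int(meta["resolution"]),
        len(bins),
        np.asarray(ii, dtype=np.int64),
        np.asarray(jj, dtype=np.int64),
        np.asarray(cc, dtype=np.int64),
    )


def write_fragment_map(fmap: FragmentMap, prefix: str | Path) -> None:
    """BED4 fragment map plus a cut-site BED with the enzyme name in col 4."""
    prefix = str(prefix)
    frag_rows = []
    for chrom in fmap.chroms:
        starts, ends = fmap.fragments(chrom)
        off = fmap._id_offset[chrom]
        frag_rows.extend(
            (chrom, int(s), int(e), off + k)
            for k, (s, e) in enumerate(zip(starts, ends))
        )
    write_bed(frag_rows, prefix + ".fragments.bed")
    cut_rows = []
    for chrom in fmap.chroms:
        for pos, name in zip(fmap.cuts[chrom], fmap.cut_labels[chrom]):
            cut_rows.append((chrom, int(pos), int(pos) + 1, name))
    write_bed(cut_rows, prefix + ".cuts.bed")


# ── flat key-value simulation config ─────────────────────────────────────

def read_config(path: str | Path) -> SimulationSpec:
    """Parse a flat ``key = value`` simulation config.

    Repeatable keys: ``loop = position:fold[:width[:position2]]`` and
    ``hotspot = position:fold[:width]``.  ``orientation_probs`` and
    ``domain_boundaries`` are comma-separated.
    """
    kw: dict = {}
    loops: list[LoopSpec] = []
    hotspots: list[HotspotSpec] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "loop":
                f = val.split(":")
                loops.append(
                    LoopSpec(
                        int(f[0]), float(f[1]),
                        int(f[2]) if len(f) > 2 else 500,
                        int(f[3]) if len(f) > 3 else None,
                    )
                )
            elif key == "hotspot":
                f = val.split(":")
                hotspots.append(
                    HotspotSpec(
                        int(f[0]), float(f[1]), int(f[2]) if len(f) > 2 else 500
                    )
                )
            elif key == "viewpoint":
                lo, hi = val.split("-")
                kw["viewpoint"] = (int(lo), int(hi))
            elif key == "orientation_probs":
                kw["orientation_probs"] = tuple(
                    float(x) for x in val.split(",")
                )
            elif key == "domain_boundaries":
                kw["domain_boundaries"] = [int(x) for x in val.split(",")]
            elif key in ("mode",):
                kw[key] = val
            elif key in ("genome_length", "seed", "n_molecules",
                         "sonication_jitter"):
                kw[key] = int(val)
            elif key in ("gc", "alpha", "domain_ratio", "trans_rate",
                         "duplication_rate"):
                kw[key] = float(val)
            else:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
    return SimulationSpec(loops=loops, hotspots=hotspots, **kw)
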