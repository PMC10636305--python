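"""Ligation contact tables and UMI deduplication.

A proximity-ligation library records, per sequenced read, the two genomic
sides of one ligation junction.  Because the library is PCR-amplified, raw
records over-count molecules; the assay's escape hatch is that sonication (or
tagmentation) breaks each molecule at a random coordinate, so the shear-break
position acts as a unique molecular identifier (UMI): two reads with the same
ligated ends *and* the same sonication end are PCR copies of one molecule.

Columns of the canonical table (the on-disk pairs-like TSV mirrors them):

====================  =====================================================
read_id               arbitrary string
chrom1/pos1/strand1   first side: chromosome, ligated restriction-cut
                      coordinate, strand
frag1                 fragment id in an attached fragment map (-1 if unset)
chrom2/pos2/strand2   second (distal, in 4C mode) side
frag2                 distal fragment id
sonication_end        shear-break coordinate on the distal side (NaN if
                      missing)
allele                'ref' / 'alt' / 'unassigned' / '.'
copies                pre-dedup multiplicity (collapsed count after dedup)
viewpoint_id          bait identifier in 4C mode, '.' otherwise
====================  =====================================================

Contacts are located at the ligated restriction-cut coordinate of each side
(the position the assay actually tags), not the fragment midpoint; all
downstream binning uses these coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import FragmentMap

logger = logging.getLogger(__name__)

__all__ = [
    "PAIRS_COLUMNS",
    "ContactTable",
    "assign_to_fragment",
    "dedup_contacts",
    "orientation_profile",
    "cis_trans_stats",
]

PAIRS_COLUMNS = [
    "read_id",
    "chrom1",
    "pos1",
    "strand1",
    "frag1",
    "chrom2",
    "pos2",
    "strand2",
    "frag2",
    "sonication_end",
    "allele",
    "copies",
]

# UMI key in 4C mode: the bait side is constant, the distal side plus the
# shear break identify the molecule.  Anchor-free (Hi-C) records have no
# constant side, so side1 joins the key (otherwise distinct contacts sharing
# a distal end would be merged).
_KEY_4C = ["viewpoint_id", "chrom2", "frag2", "pos2", "strand2", "sonication_end"]
_KEY_HIC = ["chrom1", "pos1", "strand1"] + _KEY_4C


@dataclass
class ContactTable:
    """An ordered collection of ligation contacts plus header metadata.

    ``meta`` carries provenance (source, enzymes, fragment-map id, and the 4C
    viewpoint interval when the table is viewpoint-anchored).
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "viewpoint_id" not in self.df.columns:
            self.df = self.df.assign(viewpoint_id=".")
        missing = [c for c in PAIRS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"contact table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_4c(self) -> bool:
        """True when any record carries a viewpoint id (bait-anchored mode)."""
        vp = self.df["viewpoint_id"]
        return bool((vp.notna() & (vp != ".")).any())

    def copy(self) -> "ContactTable":
        return ContactTable(self.df.copy(), dict(self.meta))


def assign_to_fragment(chrom: str, coordinate: int, fmap: FragmentMap) -> int:
    """Global id of the fragment whose half-open interval holds ``coordinate``."""
    return fmap.fragment_id(chrom, coordinate)


def dedup_contacts(table: ContactTable) -> ContactTable:
    """Collapse PCR duplicates on the sonication-end UMI key.

    Records sharing the full key (viewpoint, distal chromosome / fragment /
    ligated-end coordinate / strand, sonication end; plus side1 for
    anchor-free tables) are merged into one surviving record whose ``copies``
    is the sum of the collapsed multiplicities.  The match is exact — no ±1 bp
    tolerance on the shear coordinate.  Records lacking a sonication end
    cannot be deduplicated and pass through unchanged; their count is logged.
    Output order is deterministic (sorted by key).
    """
    df = table.df
    key = _KEY_4C if table.is_4c else _KEY_HIC
    has_umi = df["sonication_end"].notna()
    n_missing = int((~has_umi).sum())
    if n_missing:
        logger.warning(
            "%d contact records lack a sonication end and were not deduplicated",
            n_missing,
        )
    dd = df[has_umi]
    if len(dd):
        first_cols = {
            c: "first" for c in df.columns if c not in key and c != "copies"
        }
        collapsed = (
            dd.groupby(key, sort=True, dropna=False)
            .agg({"copies": "sum", **first_cols})
            .reset_index()
        )
        collapsed = collapsed[list(df.columns)]
    else:
        collapsed = dd
    out = pd.concat([collapsed, df[~has_umi]], ignore_index=True)
    meta = dict(table.meta)
    meta["deduplicated"] = True
    return ContactTable(out, meta)


def orientation_profile(
    table: ContactTable,
    bin_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Strand-orientation composition of cis contacts by genomic distance.

    For a pair ordered ``pos1 < pos2`` the read orientations classify the
    junction: side1 on '-' points away from the partner ("out"), side2 on '+'
    likewise.  Short-range ligation artefacts (e.g. self-circularisation)
    show up as strong out–out excess below ~10 kb, so this profile is the
    standard library diagnostic.

    Returns a DataFrame with one row per log-spaced distance bin and columns
    ``in_in, in_out, out_in, out_out`` (frequencies summing to 1 per occupied
    bin) plus ``n`` contacts per bin.
    """
    df = table.df
    cis = df[df["chrom1"] == df["chrom2"]]
    if bin_edges is None:
        bin_edges = np.logspace(2, 7, 26)  # 100 bp .. 10 Mb
    if cis.empty:
        return pd.DataFrame(
            columns=["dist_lo", "dist_hi", "n", "in_in", "in_out", "out_in", "out_out"]
        )
    p1 = cis["pos1"].to_numpy()
    p2 = cis["pos2"].to_numpy()
    s1 = cis["strand1"].to_numpy()
    s2 = cis["strand2"].to_numpy()
    swap = p1 > p2
    s1, s2 = np.where(swap, s2, s1), np.where(swap, s1, s2)
    dist = np.abs(p2 - p1)
    left_out = s1 == "-"
    right_out = s2 == "+"
    cat = np.where(
        left_out,
        np.where(right_out, "out_out", "out_in"),
        np.where(right_out, "in_out", "in_in"),
    )
    idx = np.digitize(dist, bin_edges) - 1
    ok = (idx >= 0) & (idx < len(bin_edges) - 1)
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = cat[ok & (idx == b)]
        n = sel.size
        row = {
            "dist_lo": bin_edges[b],
            "dist_hi": bin_edges[b + 1],
            "n": n,
        }
        for c in ("in_in", "in_out", "out_in", "out_out"):
            row[c] = float((sel == c).sum() / n) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cis_trans_stats(table: ContactTable) -> dict:
    """Fraction of cis contacts, overall and per viewpoint.

    In 4C mode a contact is cis when the distal side lies on the viewpoint's
    chromosome; anchor-free, when both sides share a chromosome.  A healthy
    viewpoint-anchored library is overwhelmingly cis (>99% in practice).
    """
    df = table.df
    if df.empty:
        return {"n": 0, "cis_fraction": np.nan, "per_viewpoint": {}}
    cis = df["chrom1"] == df["chrom2"]
    per_vp = {}
    if table.is_4c:
        for vp, grp in cis.groupby(df["viewpoint_id"]):
            per_vp[vp] = float(grp.mean())
    return {
        "n": int(len(df)),
        "cis_fraction": float(cis.mean()),
        "per_viewpoint": per_vp,
    }
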