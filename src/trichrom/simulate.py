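"""Synthetic genomes and ligation libraries with known ground truth.

Every caller in this package is validated against libraries whose loops,
hotspots, domains and duplication are injected by construction.  The
simulator draws ligation partners among *restriction-cut coordinates* of a
digested genome (the assay can only tag cut sites), with contact probability
shaped by:

* power-law distance decay, P ∝ d^(−α) with α = 1 by default (the typical
  intra-TAD regime; real maps show an overall log-linear decay without a
  single published exponent, so α is configurable);
* multiplicative loop folds on anchor windows (the probability is modified
  *before* restriction to cut sites);
* per-site hotspot marginal folds h, acting as h_i·h_j on pair weights;
* a same-domain contact ratio for block/domain structure;
* multinomial read-orientation sampling.

Sonication ends are drawn uniformly within ±300 bp of the ligated cut, and
PCR duplicates (exact copies, new read ids) are appended at a chosen rate.
The returned ground-truth ledger records the number of *distinct UMI keys*
among true molecules — two molecules that collide on the full UMI key are
counted once, exactly as any UMI-based assay would see them — so
deduplication can be checked exactly.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
generator per call, so a seed fully determines the output across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import PAIRS_COLUMNS, ContactTable
from .digest import FragmentMap, cut_catchment

__all__ = [
    "LoopSpec",
    "HotspotSpec",
    "SimulationSpec",
    "make_genome",
    "simulate_tri4c",
    "simulate_trihic",
]

_MAX_PAIRS = 40_000_000  # pair-weight table guard (~320 MB of float64)


@dataclass(frozen=True)
class LoopSpec:
    """An injected loop: 4C mode uses ``position`` (distal anchor only);
    Hi-C mode uses ``position`` and ``position2`` (both anchors)."""

    position: int
    fold: float
    width: int = 500
    position2: int | None = None

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("loop fold must be positive")


@dataclass(frozen=True)
class HotspotSpec:
    """An injected distal-interactivity hotspot (marginal fold on one site)."""

    position: int
    fold: float
    width: int = 500

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("hotspot fold must be positive")


@dataclass
class SimulationSpec:
    """Parameters of one synthetic ligation library."""

    mode: str = "4c"                       # "4c" | "hic"
    genome_length: int = 1_000_000
    gc: float = 0.5
    seed: int = 0
    n_molecules: int = 100_000
    viewpoint: tuple[int, int] | None = None
    alpha: float = 1.0                     # decay exponent
    loops: list[LoopSpec] = field(default_factory=list)
    hotspots: list[HotspotSpec] = field(default_factory=list)
    domain_boundaries: list[int] = field(default_factory=list)
    domain_ratio: float = 1.0              # same-domain weight multiplier
    trans_rate: float = 0.0
    duplication_rate: float = 0.0
    orientation_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    sonication_jitter: int = 300

    def __post_init__(self) -> None:
        if not 0 <= self.trans_rate < 1 or not 0 <= self.duplication_rate < 1:
            raise ValueError("rates must lie in [0, 1)")
        op = np.asarray(self.orientation_probs, dtype=float)
        if op.shape != (4,) or np.any(op < 0) or not np.isclose(op.sum(), 1.0):
            raise ValueError("orientation_probs must be a 4-vector summing to 1")


def make_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """An i.i.d. random nucleotide sequence with the given GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)
    return bases.tobytes().decode("ascii")


# ── orientation categories, ordered (in_in, in_out, out_in, out_out) ──
# for a pair ordered p1 < p2: side1 '+' reads toward the partner ("in"),
# side2 '-' likewise; the strand pairs below encode the four categories.
_ORIENT_STRANDS = [("+", "-"), ("+", "+"), ("-", "-"), ("-", "+")]


def _add_duplicates(
    df: pd.DataFrame, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Append PCR copies so duplicates are ~``rate`` of all reads."""
    if rate <= 0 or df.empty:
        return df
    n = len(df)
    n_dup = int(round(n * rate / (1 - rate)))
    if n_dup == 0:
        return df
    picks = rng.integers(0, n, size=n_dup)
    dups = df.iloc[picks].copy()
    dups["read_id"] = [f"d{k}" for k in range(n_dup)]
    out = pd.concat([df, dups], ignore_index=True)
    return out.iloc[rng.permutation(len(out))].reset_index(drop=True)


def _weighted_draw(
    weights: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(weights)
    if cum[-1] <= 0:
        raise ValueError("all pair weights are zero")
    return np.searchsorted(cum, rng.random(size) * cum[-1], side="right")


def simulate_tri4c(
    spec: SimulationSpec,
    fmap: FragmentMap,
    chrom: str | None = None,
) -> tuple[ContactTable, dict]:
    """Draw a viewpoint-anchored (4C) library from a fragment map.

    Each molecule picks a bait cut inside the viewpoint interval and a
    distal cut with probability ∝ d^(−α) times any loop fold whose window
    covers the cut; the sonication end is uniform within ±jitter of the
    distal cut.  Returns the pre-dedup table and a ground-truth ledger with
    the distinct-UMI molecule count and the injected feature list.
    """
    if spec.viewpoint is None:
        raise ValueError("4C simulation requires a viewpoint interval")
    chrom = chrom or fmap.chroms[0]
    rng = np.random.default_rng(spec.seed)
    cuts = fmap.cut_positions(chrom)
    lo, hi = spec.viewpoint
    bait_cuts = cuts[(cuts >= lo) & (cuts < hi)]
    if bait_cuts.size == 0:
        raise ValueError("viewpoint interval contains no restriction cut site")
    center = (lo + hi) / 2
    d = np.abs(cuts - center)
    distal_ok = (cuts < lo) | (cuts >= hi)
    catch = cut_catchment(fmap, chrom, spec.sonication_jitter)
    w = catch * np.where(distal_ok, np.maximum(d, 1.0) ** (-spec.alpha), 0.0)
    for loop in spec.loops:
        in_win = np.abs(cuts - loop.position) <= loop.width / 2
        w = np.where(in_win, w * loop.fold, w)

    n = spec.n_molecules
    trans_chroms = [c for c in fmap.chroms if c != chrom]
    is_trans = (
        rng.random(n) < spec.trans_rate if trans_chroms and spec.trans_rate > 0
        else np.zeros(n, dtype=bool)
    )
    n_cis = int((~is_trans).sum())

    idx = _weighted_draw(w, n_cis, rng)
    chrom2 = np.full(n, chrom, dtype=object)
    pos2_all = np.empty(n, dtype=np.int64)
    pos2_all[~is_trans] = cuts[idx]
    n_trans = n - n_cis
    if n_trans:
        trans_idx = np.flatnonzero(is_trans)
        tc = rng.integers(0, len(trans_chroms), size=n_trans)
        for k, c in enumerate(trans_chroms):
            sel = tc == k
            if not sel.any():
                continue
            ccuts = fmap.cut_positions(c)
            if ccuts.size == 0:
                raise ValueError(f"trans chromosome {c} has no cut sites")
            pos2_all[trans_idx[sel]] = ccuts[
                rng.integers(0, len(ccuts), size=int(sel.sum()))
            ]
            chrom2[trans_idx[sel]] = c

    pos1 = bait_cuts[rng.integers(0, len(bait_cuts), size=n)]
    strand2 = np.where(rng.random(n) < 0.5, "+", "-")
    j = spec.sonication_jitter
    son = pos2_all + rng.integers(-j, j + 1, size=n)

    frag2 = np.full(n, -1, dtype=np.int64)
    for c in np.unique(chrom2):
        sel = chrom2 == c
        frag2[sel] = fmap.fragment_ids(
            str(c), np.clip(pos2_all[sel], 0, fmap.chrom_lengths[str(c)] - 1)
        )
    frag1 = fmap.fragment_ids(chrom, pos1)

    df = pd.DataFrame(
        {
            "read_id": [f"m{k}" for k in range(n)],
            "chrom1": chrom,
            "pos1": pos1,
            "strand1": "+",
            "frag1": frag1,
            "chrom2": chrom2,
            "pos2": pos2_all,
            "strand2": strand2,
            "frag2": frag2,
            "sonication_end": son.astype(float),
            "allele": ".",
            "copies": 1,
            "viewpoint_id": "vp",
        }
    )
    key = ["viewpoint_id", "chrom2", "frag2", "pos2", "strand2", "sonication_end"]
    n_unique = int(df.groupby(key, sort=False).ngroups)
    out = _add_duplicates(df, spec.duplication_rate, rng)
    ledger = {
        "n_molecules": n,
        "n_unique_umi": n_unique,
        "n_reads": len(out),
        "loops": list(spec.loops),
        "viewpoint": spec.viewpoint,
        "alpha": spec.alpha,
    }
    table = ContactTable(
        out, {"mode": "4c", "viewpoint": (chrom, lo, hi), "seed": spec.seed}
    )
    return table, ledger


def _pair_weights(
    pos: np.ndarray, catch: np.ndarray, spec: SimulationSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangular pair index arrays and their sampling weights."""
    m = len(pos)
    n_pairs = m * (m - 1) // 2
    if n_pairs > _MAX_PAIRS:
        raise ValueError(
            f"{n_pairs} site pairs exceed the in-memory limit; use a smaller genome"
        )
    ii, jj = np.triu_indices(m, 1)
    d = (pos[jj] - pos[ii]).astype(float)
    w = catch[ii] * catch[jj] * np.maximum(d, 1.0) ** (-spec.alpha)

    h = np.ones(m)
    for hs in spec.hotspots:
        h[np.abs(pos - hs.position) <= hs.width / 2] *= hs.fold
    w *= h[ii] * h[jj]

    if spec.domain_boundaries and spec.domain_ratio != 1.0:
        block = np.searchsorted(np.asarray(spec.domain_boundaries), pos, "right")
        w = np.where(block[ii] == block[jj], w * spec.domain_ratio, w)

    for loop in spec.loops:
        if loop.position2 is None:
            raise ValueError("Hi-C loop specs need both anchors (position2)")
        a = np.abs(pos - loop.position) <= loop.width / 2
        b = np.abs(pos - loop.position2) <= loop.width / 2
        if (a & b).any():
            raise ValueError("loop anchor windows overlap; contradictory spec")
        hit = (a[ii] & b[jj]) | (b[ii] & a[jj])
        w = np.where(hit, w * loop.fold, w)
    return ii, jj, w


def simulate_trihic(
    spec: SimulationSpec,
    fmap: FragmentMap,
    chrom: str | None = None,
) -> tuple[ContactTable, dict]:
    """Draw an anchor-free (Hi-C) cis library from a fragment map.

    Pairs of cut sites (i < j) are sampled with probability
    ∝ d^(−α) · domain factor · h_i h_j · loop fold, orientations from the
    4-vector, sonication end within ±jitter of side2.  Returns the
    pre-dedup table and the ground-truth ledger.
    """
    chrom = chrom or fmap.chroms[0]
    rng = np.random.default_rng(spec.seed)
    pos = fmap.cut_positions(chrom)
    ii, jj, w = _pair_weights(pos, cut_catchment(fmap, chrom, spec.sonication_jitter), spec)
    n = spec.n_molecules
    draw = _weighted_draw(w, n, rng)
    p1 = pos[ii[draw]]
    p2 = pos[jj[draw]]

    cat = rng.choice(4, size=n, p=np.asarray(spec.orientation_probs))
    s1 = np.array([_ORIENT_STRANDS[c][0] for c in cat])
    s2 = np.array([_ORIENT_STRANDS[c][1] for c in cat])
    j = spec.sonication_jitter
    son = p2 + rng.integers(-j, j + 1, size=n)

    frag1 = fmap.fragment_ids(chrom, p1)
    frag2 = fmap.fragment_ids(chrom, p2)
    df = pd.DataFrame(
        {
            "read_id": [f"m{k}" for k in range(n)],
            "chrom1": chrom,
            "pos1": p1,
            "strand1": s1,
            "frag1": frag1,
            "chrom2": chrom,
            "pos2": p2,
            "strand2": s2,
            "frag2": frag2,
            "sonication_end": son.astype(float),
            "allele": ".",
            "copies": 1,
            "viewpoint_id": ".",
        }
    )
    key = ["chrom1", "pos1", "strand1", "chrom2", "frag2", "pos2", "strand2",
           "sonication_end"]
    n_unique = int(df.groupby(key, sort=False).ngroups)
    out = _add_duplicates(df, spec.duplication_rate, rng)
    ledger = {
        "n_molecules": n,
        "n_unique_umi": n_unique,
        "n_reads": len(out),
        "loops": list(spec.loops),
        "hotspots": list(spec.hotspots),
        "domain_boundaries": list(spec.domain_boundaries),
        "alpha": spec.alpha,
    }
    table = ContactTable(out, {"mode": "hic", "seed": spec.seed})
    return table, ledger
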