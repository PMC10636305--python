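"""Matrix-level analytics for all-vs-all (Hi-C style) contact data.

High-resolution multi-enzyme Hi-C resolves three classes of sub-TAD
microstructure that this module quantifies:

* **Distal-interactivity hotspots** — 100 bp bins whose long-range contact
  ends are enriched over the 5–50 kb local background; these anchor the
  nonspecific interaction "stripes" radiating from active regulatory
  elements.  Called with the same Poisson machinery as the 4C loop caller at
  a stringent genome-wide Bonferroni threshold (p < 3e-7 by default).
* **Loops** — point contacts between two elements.  Genome-wide 2D loop
  discovery is delegated to external tools (loop lists arrive as BEDPE);
  within this package loops are found through virtual 4C extraction plus the
  1D caller, and scored in aggregate by Z-scored APA.
* **Domains** — insulation-score minima mark boundaries of (micro)domains.

The stripe-residual decomposition asks whether a loop's enrichment exceeds
the product of its two anchors' nonspecific interactivities — i.e. whether
the loop is a specific structure rather than incidental colocalisation of
two sticky loci — and loop asymmetry measures how strongly each anchor
blocks its partner's stripe from extending past the loop.

Observed/expected throughout uses the per-diagonal mean (distance-decay
expectation); iterative matrix balancing is deliberately not applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactTable
from .fourc import (
    InteractionProfile,
    bin_profile,
    local_background_track,
    DEFAULT_SCALES,
    DEFAULT_EXCLUSION,
    DEFAULT_FLOOR,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "HotspotTrack",
    "APAResult",
    "bin_matrix",
    "virtual_4c",
    "distal_interactivity",
    "insulation_track",
    "apa",
    "stripe_residual",
    "loop_asymmetry",
    "HOTSPOT_P_THRESHOLD",
]

#: Genome-wide Bonferroni significance threshold for hotspot calling.
HOTSPOT_P_THRESHOLD = 3e-7


@dataclass
class ContactMatrix:
    """Sparse symmetric binned contact counts for one chromosome.

    Entries are stored upper-triangular (``bin_i <= bin_j``), unique per
    pair; symmetry is implied on query.
    """

    chrom: str
    resolution: int
    n_bins: int
    bin_i: np.ndarray
    bin_j: np.ndarray
    count: np.ndarray
    total: int = 0

    def __post_init__(self) -> None:
        if self.total == 0:
            self.total = int(self.count.sum())

    def dense(self) -> np.ndarray:
        """Full symmetric dense matrix (float)."""
        m = np.zeros((self.n_bins, self.n_bins))
        m[self.bin_i, self.bin_j] = self.count
        low = self.bin_i != self.bin_j
        m[self.bin_j[low], self.bin_i[low]] = self.count[low]
        return m

    def expected_by_distance(
        self, exclude: Sequence[tuple[int, int, int]] = (),
    ) -> np.ndarray:
        """Mean count per diagonal d = |i - j| (distance-decay expectation).

        ``exclude`` lists pixel neighbourhoods ``(bin_i, bin_j, flank)`` —
        typically known loop pixels — left out of the diagonal means so that
        strong point features do not inflate their own expectation (which
        matters on short chromosomes where a diagonal holds few pixels).
        """
        n = self.n_bins
        sums = np.zeros(n)
        np.add.at(sums, self.bin_j - self.bin_i, self.count)
        counts = (n - np.arange(n)).astype(float)
        if exclude:
            dense = self.dense()
            seen: set[tuple[int, int]] = set()
            for bi, bj, f in exclude:
                lo_i, hi_i = max(bi - f, 0), min(bi + f, n - 1)
                lo_j, hi_j = max(bj - f, 0), min(bj + f, n - 1)
                for a in range(lo_i, hi_i + 1):
                    for b in range(lo_j, hi_j + 1):
                        a2, b2 = min(a, b), max(a, b)
                        if (a2, b2) in seen:
                            continue
                        seen.add((a2, b2))
                        sums[b2 - a2] -= dense[a2, b2]
                        counts[b2 - a2] -= 1
        return sums / np.maximum(counts, 1.0)

    def oe(
        self,
        floor: float = 1e-12,
        exclude: Sequence[tuple[int, int, int]] = (),
    ) -> np.ndarray:
        """Dense observed/expected matrix under the distance-decay expectation."""
        exp = self.expected_by_distance(exclude)
        dense = self.dense()
        n = self.n_bins
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        return dense / np.maximum(exp[d], floor)

    def rebin(self, resolution: int) -> "ContactMatrix":
        """Aggregate to a coarser resolution (must be a multiple)."""
        if resolution % self.resolution != 0:
            raise ValueError("new resolution must be a multiple of the current one")
        f = resolution // self.resolution
        i = self.bin_i // f
        j = self.bin_j // f
        n = -(-self.n_bins // f)
        key = i * n + j
        uniq, inv = np.unique(key, return_inverse=True)
        counts = np.zeros(len(uniq), dtype=np.int64)
        np.add.at(counts, inv, self.count)
        return ContactMatrix(
            self.chrom, resolution, n, uniq // n, uniq % n, counts
        )


def bin_matrix(
    table: ContactTable,
    resolution: int,
    chrom: str | None = None,
    chrom_length: int | None = None,
) -> ContactMatrix:
    """Bin the cis contacts of one chromosome into a symmetric sparse matrix.

    Entry (i, j) with i <= j counts contacts whose two ligated-end
    coordinates fall in bins i and j; the total is preserved.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    df = table.df
    cis = df[df["chrom1"] == df["chrom2"]]
    if chrom is None:
        chroms = cis["chrom1"].unique()
        if len(chroms) != 1:
            raise ValueError("table spans multiple chromosomes; pass chrom=")
        chrom = str(chroms[0])
    cis = cis[cis["chrom1"] == chrom]
    p1 = cis["pos1"].to_numpy(dtype=np.int64)
    p2 = cis["pos2"].to_numpy(dtype=np.int64)
    if chrom_length is None:
        chrom_length = int(max(p1.max(initial=0), p2.max(initial=0))) + 1
    n = -(-chrom_length // resolution)
    i = p1 // resolution
    j = p2 // resolution
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    key = lo * n + hi
    uniq, inv = np.unique(key, return_inverse=True)
    counts = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(counts, inv, 1)
    return ContactMatrix(chrom, resolution, int(n), uniq // n, uniq % n, counts)


def virtual_4c(
    table: ContactTable,
    viewpoint: tuple[str, int, int],
    step: int = 100,
    window: int = 500,
    region: tuple[int, int] | None = None,
) -> InteractionProfile:
    """Extract a viewpoint profile from anchor-free contacts.

    Contacts with exactly one ligated end inside the viewpoint interval are
    re-anchored (viewpoint side becomes side1) and binned exactly like a
    native 4C profile, so downstream loop calling is shared with the 1D
    caller.
    """
    chrom, lo, hi = viewpoint
    if hi <= lo:
        raise ValueError("empty viewpoint interval")
    df = table.df
    cis = df[(df["chrom1"] == chrom) & (df["chrom2"] == chrom)]
    in1 = (cis["pos1"] >= lo) & (cis["pos1"] < hi)
    in2 = (cis["pos2"] >= lo) & (cis["pos2"] < hi)
    touch = cis[in1 ^ in2]
    swap = ((touch["pos2"] >= lo) & (touch["pos2"] < hi)).to_numpy()
    sub = touch.copy()
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"),
                 ("strand1", "strand2"), ("frag1", "frag2")):
        va, vb = sub[a].to_numpy().copy(), sub[b].to_numpy().copy()
        sub[a] = np.where(swap, vb, va)
        sub[b] = np.where(swap, va, vb)
    sub = sub.assign(viewpoint_id="virtual")
    vtable = ContactTable(sub, {**table.meta, "viewpoint": viewpoint})
    return bin_profile(
        vtable, viewpoint, step=step, window=window, region=region,
        viewpoint_id="virtual",
    )


@dataclass
class HotspotTrack:
    """Per-bin distal interactivity with hotspot flags.

    ``df`` columns: ``start``, ``raw`` (distal ends per step bin), ``D``
    (windowed count), ``E`` (local-background expectation), ``p``, ``S``
    (−log10 p), ``hotspot``.  ``intervals`` are merged runs of flagged bins.
    """

    chrom: str
    step: int
    window: int
    region: tuple[int, int]
    min_dist: int
    p_threshold: float
    df: pd.DataFrame
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def fe_at(self, pos: int, match_within: int = 1000) -> float:
        """Anchor interactivity D/E at the hotspot bin nearest ``pos``.

        Searches flagged bins within ``match_within`` bp; falls back to the
        bin containing ``pos`` itself when none is flagged nearby.
        """
        df = self.df
        starts = df["start"].to_numpy()
        centers = starts + self.step / 2
        flagged = df["hotspot"].to_numpy()
        idx = None
        if flagged.any():
            cand = np.flatnonzero(flagged)
            dist = np.abs(centers[cand] - pos)
            best = np.argmin(dist)
            if dist[best] <= match_within:
                idx = cand[best]
        if idx is None:
            idx = int(np.clip((pos - self.region[0]) // self.step, 0, len(df) - 1))
        d = df["D"].iloc[idx]
        e = df["E"].iloc[idx]
        return float(d / e) if e > 0 else np.nan


def distal_interactivity(
    table: ContactTable,
    resolution: int = 100,
    window: int = 500,
    min_dist: int = 10_000,
    p_threshold: float = HOTSPOT_P_THRESHOLD,
    region: tuple[int, int] | None = None,
    chrom: str | None = None,
    scales: Sequence[int] = DEFAULT_SCALES,
    exclusion: int = DEFAULT_EXCLUSION,
    floor: float = DEFAULT_FLOOR,
    fragment_map=None,
) -> HotspotTrack:
    """Call distal-interactivity hotspots at 100 bp resolution.

    D(bin) counts contact *ends* in the bin's 500 bp window whose partner
    lies at least ``min_dist`` away (both ends of a sufficiently long-range
    contact contribute, each at its own coordinate).  The expectation E
    comes from the same max-over-scales 5–50 kb local background as the
    loop caller, applied to the D track; p is the exact Poisson upper tail
    and S = −log10 p.  Bins with p below the stringent Bonferroni-style
    threshold (default 3e-7) are flagged and adjacent flagged bins merged
    into hotspot intervals.  As in the loop caller, passing the digestion
    ``fragment_map`` corrects E for restriction-site structure (taggable
    mass per window).
    """
    df = table.df
    cis = df[df["chrom1"] == df["chrom2"]]
    if chrom is None:
        chroms = cis["chrom1"].unique()
        if len(chroms) != 1:
            raise ValueError("table spans multiple chromosomes; pass chrom=")
        chrom = str(chroms[0])
    cis = cis[cis["chrom1"] == chrom]
    p1 = cis["pos1"].to_numpy(dtype=np.int64)
    p2 = cis["pos2"].to_numpy(dtype=np.int64)
    far = np.abs(p2 - p1) >= min_dist
    ends = np.concatenate([p1[far], p2[far]])
    if region is None:
        upper = int(max(p1.max(initial=0), p2.max(initial=0))) + 1
        region = (0, -(-upper // resolution) * resolution)
    rstart, rend = region
    n_bins = (rend - rstart) // resolution
    inside = (ends >= rstart) & (ends < rend)
    raw = np.bincount(
        (ends[inside] - rstart) // resolution, minlength=n_bins
    ).astype(np.int64)
    half_bins = (window // resolution - 1) // 2
    S_cum = np.concatenate(([0], np.cumsum(raw)))
    i = np.arange(n_bins)
    lo = np.clip(i - half_bins, 0, n_bins)
    hi = np.clip(i + half_bins + 1, 0, n_bins)
    D = S_cum[hi] - S_cum[lo]
    mass = None
    if fragment_map is not None:
        from .digest import tag_mass_track

        mass = tag_mass_track(fragment_map, chrom, (rstart, rend), resolution)
    E = local_background_track(
        raw, resolution, window, scales, exclusion, floor, mass
    )
    p = stats.poisson.sf(D - 1, E)
    with np.errstate(divide="ignore"):
        score = np.where(p > 0, -np.log10(p), 350.0)
    flag = p < p_threshold
    starts = rstart + resolution * np.arange(n_bins)
    out = pd.DataFrame(
        {"start": starts, "raw": raw, "D": D, "E": E, "p": p, "S": score,
         "hotspot": flag}
    )
    intervals: list[tuple[int, int]] = []
    idx = np.flatnonzero(flag)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.r_[idx[0], idx[breaks + 1]]
        run_ends = np.r_[idx[breaks], idx[-1]]
        intervals = [
            (int(starts[a]), int(starts[b]) + resolution)
            for a, b in zip(run_starts, run_ends)
        ]
    return HotspotTrack(
        chrom, resolution, window, (rstart, rend), min_dist, p_threshold,
        out, intervals,
    )


@dataclass
class InsulationTrack:
    """Per-bin insulation scores with called boundaries."""

    chrom: str
    resolution: int
    window_bins: int
    df: pd.DataFrame                     # start, diamond, score
    boundaries: pd.DataFrame             # bin, start, score, delta


def insulation_track(
    matrix: ContactMatrix,
    window_bins: int = 25,
    delta_threshold: float = 0.1,
) -> InsulationTrack:
    """Diamond insulation scores and boundary calls.

    diamond(i) is the mean count over the w×w square of pairs (a, b) with
    i−w <= a < i < b <= i+w — the contacts that *cross* bin i.  The score is
    log2(diamond / chromosome-wide mean diamond), so it averages ~0 and
    minima mark positions that contacts rarely cross, i.e. boundaries.
    Boundaries are (plateau-aware) local minima whose depth below the
    maximal neighbouring score within w bins on both sides exceeds
    ``delta_threshold``; for a plateau of equal minima the midpoint bin is
    reported.
    """
    n = matrix.n_bins
    w = int(window_bins)
    if w < 1 or 2 * w >= n:
        raise ValueError("window_bins must satisfy 1 <= w < n_bins/2")
    dense = matrix.dense()
    # integral image for O(1) rectangle sums
    I = np.zeros((n + 1, n + 1))
    I[1:, 1:] = dense.cumsum(0).cumsum(1)

    def rect(a0, a1, b0, b1):  # sum over rows [a0,a1), cols [b0,b1)
        return I[a1, b1] - I[a0, b1] - I[a1, b0] + I[a0, b0]

    diamond = np.full(n, np.nan)
    for i in range(w, n - w):
        diamond[i] = rect(i - w, i, i + 1, i + w + 1) / (w * w)
    valid = ~np.isnan(diamond)
    mean_d = np.nanmean(diamond)
    if mean_d <= 0:
        raise ValueError("matrix has no contacts in any diamond")
    with np.errstate(divide="ignore"):
        score = np.where(valid, np.log2(np.maximum(diamond, 1e-12) / mean_d), np.nan)

    # plateau-aware local minima
    rows = []
    vi = np.flatnonzero(valid)
    s = score[vi]
    k = 0
    while k < len(s):
        k2 = k
        while k2 + 1 < len(s) and s[k2 + 1] == s[k]:
            k2 += 1
        left_ok = k > 0 and s[k - 1] > s[k]
        right_ok = k2 < len(s) - 1 and s[k2 + 1] > s[k]
        if left_ok and right_ok:
            i0, i1 = vi[k], vi[k2]
            b = (i0 + i1 + 1) // 2
            lo = max(vi[0], i0 - w)
            hi = min(vi[-1], i1 + w)
            neigh = np.nanmax(
                np.concatenate([score[lo:i0], score[i1 + 1 : hi + 1]])
            )
            delta = float(neigh - s[k])
            if delta > delta_threshold:
                rows.append(
                    {"bin": int(b), "start": int(b * matrix.resolution),
                     "score": float(s[k]), "delta": delta}
                )
        k = k2 + 1

    starts = matrix.resolution * np.arange(n)
    df = pd.DataFrame({"start": starts, "diamond": diamond, "score": score})
    return InsulationTrack(
        matrix.chrom, matrix.resolution, w, df,
        pd.DataFrame(rows, columns=["bin", "start", "score", "delta"]),
    )


@dataclass
class APAResult:
    """Aggregated observed/expected around loop pixels, with Z transform."""

    matrix: np.ndarray        # (2k+1)x(2k+1) mean O/E
    z: np.ndarray             # Z-scores from off-center cells
    center_fe: float          # central 3x3 mean over lower-left corner 3x3 mean
    n_loops: int


def apa(
    matrix: ContactMatrix,
    loops: Sequence[tuple[int, int]],
    flank_bins: int = 10,
) -> APAResult:
    """Aggregate peak analysis of a loop list on one matrix.

    Each usable loop pixel (anchor midpoints binned at the matrix
    resolution, at least flank+2 bins off the diagonal and with full flanks
    inside the matrix) contributes its (2k+1)² observed/expected
    neighbourhood; the element-wise mean is returned.  Center fold
    enrichment is the mean of the central 3×3 divided by the mean of the
    lower-left corner 3×3 (the corner nearest the diagonal, i.e. the
    shortest-distance background).  The Z matrix standardises every cell
    against the mean and s.d. of the non-central cells.
    """
    k = int(flank_bins)
    oe = matrix.oe()
    n = matrix.n_bins
    stack = []
    for a1, a2 in loops:
        bi, bj = sorted((a1 // matrix.resolution, a2 // matrix.resolution))
        if bj - bi < k + 2:
            continue
        if bi - k < 0 or bj + k >= n:
            continue
        stack.append(oe[bi - k : bi + k + 1, bj - k : bj + k + 1])
    if not stack:
        raise ValueError("no usable loops for APA")
    mean = np.mean(stack, axis=0)
    c = k
    center_mask = np.zeros_like(mean, dtype=bool)
    center_mask[c - 1 : c + 2, c - 1 : c + 2] = True
    corner = mean[-3:, :3]
    center_fe = float(mean[center_mask].mean() / corner.mean())
    off = mean[~center_mask]
    if off.size and off.std(ddof=0) > 0:
        z = (mean - off.mean()) / off.std(ddof=0)
    else:  # k = 1: every cell is central, no off-center reference
        z = np.full_like(mean, np.nan)
    return APAResult(mean, z, center_fe, len(stack))


def stripe_residual(
    loops: Sequence[tuple[int, int, float | None]],
    track: HotspotTrack,
    matrix: ContactMatrix | None = None,
    match_within: int = 1000,
    anchor_fe: str = "track",
    band_bins: int = 1,
) -> pd.DataFrame:
    """Decompose loop enrichment into anchor-stripe products.

    For each loop ``(anchor1_pos, anchor2_pos, fe_loop)`` the residual is
    ``FE_loop / (FE_a1 · FE_a2)`` where FE_a is the anchor's nonspecific
    distal interactivity fold enrichment — D/E at the nearest hotspot bin
    within ``match_within`` bp (else the anchor's own bin).  A residual of 1
    means the loop pixel is exactly what two independently sticky anchors
    would produce; residuals above 1 indicate loop-specific structure.

    ``fe_loop`` may be None when ``matrix`` is given, in which case the
    loop's central 3×3 mean observed/expected is used; the loop pixels
    themselves are excluded from the distance-decay expectation so strong
    loops do not inflate their own background.  With ``anchor_fe="band"``
    the anchor strength is instead measured on the matrix as the mean O/E
    of the anchor's row band (±``band_bins``) over distal columns, for
    comparison with the 1D definition.
    """
    rows = []
    oe = None
    if matrix is not None:
        pix = [
            (*sorted((a1 // matrix.resolution, a2 // matrix.resolution)), 2)
            for a1, a2, _ in loops
        ]
        oe = matrix.oe(exclude=pix)
    for idx, (a1, a2, fe) in enumerate(loops):
        if fe is None:
            if oe is None:
                raise ValueError("fe_loop missing and no matrix supplied")
            bi, bj = sorted((a1 // matrix.resolution, a2 // matrix.resolution))
            fe = float(
                oe[max(bi - 1, 0) : bi + 2, max(bj - 1, 0) : bj + 2].mean()
            )
        if anchor_fe == "track":
            fa1 = track.fe_at(a1, match_within)
            fa2 = track.fe_at(a2, match_within)
        elif anchor_fe == "band":
            if oe is None:
                raise ValueError('anchor_fe="band" requires a matrix')
            min_bins = track.min_dist // matrix.resolution
            fa1 = _band_fe(oe, a1 // matrix.resolution, band_bins, min_bins)
            fa2 = _band_fe(oe, a2 // matrix.resolution, band_bins, min_bins)
        else:
            raise ValueError(f"unknown anchor_fe mode {anchor_fe!r}")
        if not (fe > 0 and fa1 > 0 and fa2 > 0):
            logger.warning("loop %d skipped: non-positive fold enrichment", idx)
            continue
        resid = fe / (fa1 * fa2)
        rows.append(
            {"loop": idx, "anchor1": a1, "anchor2": a2, "FE_loop": fe,
             "FE_a1": fa1, "FE_a2": fa2, "residual": resid,
             "log2_residual": float(np.log2(resid))}
        )
    return pd.DataFrame(rows)


def _band_fe(oe: np.ndarray, b: int, band_bins: int, min_dist_bins: int) -> float:
    n = oe.shape[0]
    rows = oe[max(0, b - band_bins) : b + band_bins + 1]
    cols = np.abs(np.arange(n) - b) >= min_dist_bins
    return float(rows[:, cols].mean())


def loop_asymmetry(
    matrix: ContactMatrix,
    loop: tuple[int, int],
    span_bins: int = 10,
    band_bins: int = 1,
) -> dict:
    """Interior/exterior stripe intensities around one loop and their ratios.

    For the left anchor (bin i of the corner pixel (i, j)), the stripe is
    the horizontal band of rows i±1; its *interior* intensity is the mean
    observed/expected over columns (j−span, j) — the stripe running from the
    corner back into the loop — and its *exterior* intensity over columns
    (j, j+span] — the stripe continuing past the partner anchor.  The right
    anchor is treated symmetrically on its vertical band (interior rows
    toward i, exterior rows beyond).  asymmetry = exterior / interior: a
    value well below 1 means the partner anchor blocks the stripe from
    extending outside the loop.  Bands truncated at the matrix edge are
    flagged.
    """
    a1, a2 = loop
    r = matrix.resolution
    i, j = sorted((a1 // r, a2 // r))
    n = matrix.n_bins
    oe = matrix.oe()
    truncated = False

    def band_mean(rows0, rows1, cols0, cols1):
        nonlocal truncated
        r0, r1 = max(0, rows0), min(n, rows1)
        c0, c1 = max(0, cols0), min(n, cols1)
        if (r0, r1, c0, c1) != (rows0, rows1, cols0, cols1):
            truncated = True
        if r1 <= r0 or c1 <= c0:
            return np.nan
        return float(oe[r0:r1, c0:c1].mean())

    b = band_bins
    res = {
        "anchor1_interior": band_mean(i - b, i + b + 1, j - span_bins, j),
        "anchor1_exterior": band_mean(i - b, i + b + 1, j + 1, j + span_bins + 1),
        "anchor2_interior": band_mean(i + 1, i + span_bins + 1, j - b, j + b + 1),
        "anchor2_exterior": band_mean(i - span_bins, i, j - b, j + b + 1),
        "truncated": False,
    }
    res["truncated"] = truncated
    res["asymmetry1"] = res["anchor1_exterior"] / res["anchor1_interior"]
    res["asymmetry2"] = res["anchor2_exterior"] / res["anchor2_interior"]
    return res
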