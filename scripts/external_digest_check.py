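#!/usr/bin/env python
"""OPTIONAL external check: digestion statistics on a real human assembly.

This script is NOT part of the test suite and requires a locally available
human genome FASTA (e.g. hg19; several GB, download it yourself).  It
digests the assembly with each single enzyme and with the triple panel and
reports, as JSON:

* mean fragment length per digestion;
* the single-enzyme / triple-digest fold reduction in mean fragment length
  (expected within roughly 1.9x-5.2x on a human assembly);
* the fraction of triple-digest fragments shorter than 500 bp (expected
  around 97%);
* the number of >1 kb under-digested gap intervals per digestion.

Usage:
    python scripts/external_digest_check.py --fasta hg19.fa --out check.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import trichrom as tc
from trichrom import io as tio

SINGLES = ["DpnII", "Csp6I", "NlaIII"]
TRIPLE = ["DpnII", "Csp6I", "NlaIII"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fasta", required=True, help="Human assembly FASTA")
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()

    genome = tio.read_fasta(args.fasta)
    results: dict = {"digestions": {}}
    for name, panel in [(e, [e]) for e in SINGLES] + [("triple", TRIPLE)]:
        fmap = tc.digest_genome(genome, tc.get_enzymes(panel))
        stats = tc.fragment_stats(fmap, short_threshold=500)
        stats["n_gap_intervals_gt_1kb"] = len(tc.gap_intervals(fmap, 1000))
        results["digestions"][name] = stats

    triple_mean = results["digestions"]["triple"]["mean_length"]
    results["fold_reduction_vs_triple"] = {
        e: results["digestions"][e]["mean_length"] / triple_mean
        for e in SINGLES
    }
    results["triple_fraction_below_500bp"] = results["digestions"]["triple"][
        "fraction_below"
    ]
    out = json.dumps(results, indent=2)
    if args.out:
        args.out.write_text(out + "\n")
    print(out)


if __name__ == "__main__":
    main()
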