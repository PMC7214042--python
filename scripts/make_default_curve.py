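"""Regenerate the packaged default power curve from in-repo simulations.

Usage: python scripts/make_default_curve.py [--seed N] [--out PATH]

Simulates structural alignments across a wide diversity range, runs the
two-set covariation test on each, bins the per-basepair (s, E-value) points
by integer s, and fits the default isotonic power(s) curve.
"""

from __future__ import annotations

import argparse
import sys
import time

import numpy as np

from covpower import (
    bin_pairs,
    fit_power_curve,
    run_test,
    substitutions,
    tree_from_alignment,
    write_curve,
)
from covpower.fixtures import structural_template


def collect_points(seed: int, n_diversities: int = 24,
                   seq_counts: tuple[int, ...] = (10, 25),
                   min_null_stats: int = 30_000) -> list[tuple[float, float]]:
    rng = np.random.default_rng(seed)
    points: list[tuple[float, float]] = []
    for k, mb in enumerate(np.linspace(0.01, 0.5, n_diversities)):
        for ns in seq_counts:
            aln = structural_template(
                seed=int(rng.integers(2**31)), n_seqs=ns, mean_branch=float(mb)
            )
            tree = tree_from_alignment(aln)
            subs = substitutions(aln, tree)
            res = run_test(
                aln, tree, structure=aln.structure(), mode="two_set",
                min_null_stats=min_null_stats,
                seed=int(rng.integers(2**31)), subs=subs,
            )
            points.extend(
                (float(r.substitutions), r.evalue) for r in res if r.in_structure
            )
    return points


def main(argv: list[str] | None = None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument("--out", default="src/covpower/data/default_power_curve.tsv")
    args = ap.parse_args(argv)
    t0 = time.time()
    points = collect_points(args.seed)
    binned = bin_pairs(points)
    curve = fit_power_curve(binned, fit_mode="isotonic")
    write_curve(curve, args.out)
    print(f"{len(points)} basepair points, {len(binned)} bins, "
          f"clamp_hi={curve.clamp_hi:g} -> {args.out} ({time.time() - t0:.0f}s)",
          file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
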