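#!/usr/bin/env python
"""Full-scale reproduction of the default-setting performance run.

Optimizes N = 10^5 barcodes of length 12 with the default weights and
reports P_WTa, P_WTb and P_DEC per repetition. At this scale a single
repetition takes hours on one core; the published medians
(P_WTa ~ 1.198e12, P_DEC ~ 87.43%) were summarized over 1000 repetitions.
Not part of the test suite.

Usage: python scripts/reproduce_full_scale.py --seed 1 --reps 1 [--n 100000]
"""

import argparse

import numpy as np

from barcodeopt import OptimizerConfig, optimize


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--reps", type=int, default=1)
    parser.add_argument("--n", type=int, default=100_000)
    parser.add_argument("--length", type=int, default=12)
    args = parser.parse_args()

    ss = np.random.SeedSequence(args.seed)
    decs = []
    for i, child in enumerate(ss.spawn(args.reps)):
        seed = int(child.generate_state(1)[0] % (2**31))
        cfg = OptimizerConfig(l=args.length, n=args.n, seed=seed)
        _, trace = optimize(cfg)
        decs.append(trace.p_dec)
        print(
            f"rep {i}: cycles={len(trace.records) - 1} "
            f"P_WTa={trace.p_wta:.4e} P_WTb={trace.p_wtb:.4e} P_DEC={trace.p_dec:.2f}%"
        )
    print(f"median P_DEC over {len(decs)} rep(s): {np.median(decs):.2f}%")


if __name__ == "__main__":
    main()
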