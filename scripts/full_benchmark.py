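#!/usr/bin/env python
"""Full 30-gene benchmark reproduction (long-running).

Simulates the 30-gene artificial network's training protocol (5 replicate
series of 50 time points), infers the complete network with the default
search budget (10 nests, 30 generations, 500 FPA iterations per candidate
fit), and scores it against the gold standard of 36 signed regulations.

Reference performance on this benchmark is TP = 32, FP = 4 on noiseless
data (TP = 32, FP = 19 at 5% noise).  The run is stochastic and depends on
the unreported initial conditions of the training series, so the pass bands
are TP >= 28 and FP <= 10 for the noiseless run.  Expect a runtime of
minutes to tens of minutes on one CPU; per-gene checkpoints allow
interrupted runs to resume.

The default here is 150 cuckoo generations, larger than the desk-scale
estimator default of 30: the outer search must locate three-regulator
combinations among C(30,3) = 4060 candidates, and at 30 generations it
explores too few of them (seed 1: TP = 25 at 30 generations vs TP = 33 at
150; the inner optimizer recovers exact parameters whenever the true
combination is proposed).  Observed result at seed 1 / 150 generations:
TP = 33, FP = 21, FN = 3, all 33 recovered signs correct.  The TP band is
met; the FP band is not — the extra calls are nuisance weights (|w|
between 0.1 and 7) on the unused slots of otherwise-correct combinations,
which the one-step objective cannot penalize because the sigmoid is flat
at the 1e-8 stopping tolerance near saturation.  See docs/methods.md for
the analysis.

Usage:
    python scripts/full_benchmark.py --seed 1 --out results/full_benchmark
    python scripts/full_benchmark.py --seed 1 --noise 0.05 --out results/full_noisy
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

from csfpa.benchmark import (
    add_noise,
    build_table1_network,
    extract_gold_standard,
    generate_dataset,
)
from csfpa.evaluation import confusion, sign_agreement
from csfpa.inference import CSFPANetworkInference

PASS_BANDS_NOISELESS = {"tp_min": 28, "fp_max": 10}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--noise", type=float, default=0.0)
    parser.add_argument("--generations", type=int, default=150)
    parser.add_argument("--fpa-iterations", type=int, default=500)
    parser.add_argument("--out", type=Path, default=Path("results/full_benchmark"))
    args = parser.parse_args()

    net = build_table1_network()
    gold = extract_gold_standard(net)
    data = generate_dataset(net, n_series=5, n_timepoints=50, seed=args.seed)
    if args.noise > 0:
        data = add_noise(data, args.noise, seed=args.seed + 1)

    args.out.mkdir(parents=True, exist_ok=True)
    est = CSFPANetworkInference(
        n_generations=args.generations,
        max_iterations=args.fpa_iterations,
        random_state=args.seed,
    )
    t0 = time.time()
    est.fit(data, checkpoint_dir=args.out / "checkpoints", progress=True)
    elapsed = time.time() - t0

    m = confusion(est.network_, gold)
    correct, flipped = sign_agreement(est.network_, gold)
    report = m.rounded() | {
        "sign_correct": correct,
        "sign_flipped": flipped,
        "noise": args.noise,
        "seed": args.seed,
        "runtime_seconds": round(elapsed, 1),
    }
    if args.noise == 0:
        report["pass"] = bool(
            m.tp >= PASS_BANDS_NOISELESS["tp_min"]
            and m.fp <= PASS_BANDS_NOISELESS["fp_max"]
        )
    (args.out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
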