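#!/usr/bin/env python
"""Treadmilling velocity and chirality recovery on synthetic rings.

Simulates rings of 0.5-um radius treadmilling at 25, 34 and 108 nm/s in
both directions (20 rings each, SNR 3, 100 frames at 3-s intervals) plus 20
static rings, runs the full kymograph pipeline blind, and tabulates how well
speeds and chirality are recovered and whether the quality gates reject the
static population.
"""

from pathlib import Path

from ftszring import workflows

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table, summary = workflows.velocity_recovery_experiment(seed=2024)
    table.to_csv(RESULTS / "velocity_recovery.csv", index=False)

    print(f"{summary['n_accepted']}/{summary['n_moving']} treadmilling rings accepted")
    print(f"median |v_hat - v|/v of accepted rings: {summary['median_rel_error_pct']:.1f}%")
    print(f"chirality correct: {summary['chirality_accuracy_pct']:.1f}% of accepted")
    print(f"static rings rejected by quality gates: {summary['static_rejection_pct']:.0f}%")
    for s in (25, 34, 108):
        print(f"  true {s:>3d} nm/s -> mean recovered "
              f"{summary[f'v_mean_recovered_{s}_nm_s']:.1f} nm/s")
    print(f"per-ring table written to {RESULTS / 'velocity_recovery.csv'}")


if __name__ == "__main__":
    main()
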