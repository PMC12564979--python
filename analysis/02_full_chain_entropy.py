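#!/usr/bin/env python
"""Validate the spatial pipeline end to end on Type-1 trials.

Draws 80 heatmap-entropy targets from the Type-1 distribution
(16.46 +/- 0.92 bits), synthesizes a fixation pattern and a 100 Hz gaze
stream per trial, then rescores every trial through the analysis chain
proper — I-DT fixation detection, sigma = 30 px Gaussian KDE over the full
1280x1024 grid, Shannon entropy in bits — and compares achieved to target
entropy.

Writes results/full_chain_entropy.csv (per-trial target vs achieved) and
prints the calibration summary.
"""

from pathlib import Path

from gazentropy import GeneratorConfig, generate_dataset

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = GeneratorConfig(seed=SEED, trials_per_participant=5, task_types=(1,))
    trials, _, streams = generate_dataset(cfg, mode="full")

    out = trials[["participant", "question_id", "target_he", "he_bits"]].copy()
    out["error_bits"] = out["he_bits"] - out["target_he"]
    out.to_csv(RESULTS / "full_chain_entropy.csv", index=False, float_format="%.6g")

    print(f"{len(trials)} Type-1 trials rescored through detection -> KDE -> entropy")
    print(f"mean achieved HE : {out['he_bits'].mean():.3f} bits "
          f"(targets drawn from 16.46 +/- 0.92)")
    print(f"mean |error|     : {out['error_bits'].abs().mean():.4f} bits; "
          f"max |error| {out['error_bits'].abs().max():.4f}")


if __name__ == "__main__":
    main()
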