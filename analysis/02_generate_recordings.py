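#!/usr/bin/env python
"""Generate the synthetic bench recordings used by the downstream analyses.

Writes (to scratch/, since raw 1 kHz waveforms are large): a 60 s larval
recording with 8 of 10 larvae active at 2 Hz, a no-larvae control, and four
constant-vibration recordings at 1-4 Hz in 1 Hz steps.
"""

import argparse
from dataclasses import replace
from pathlib import Path

from larvasense import synthetic as syn
from larvasense.waveform import write_waveform_csv

SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--duration", type=float, default=60.0)
    args = parser.parse_args()
    SCRATCH.mkdir(exist_ok=True)

    cfg = syn.RecordingConfig(duration=args.duration, seed=args.seed)
    motion, noise = syn.LarvaMotionSpec(), syn.NoiseModel()

    active = syn.generate_recording(cfg, motion, noise)
    write_waveform_csv(active, SCRATCH / "larvae.csv")
    print(f"larvae.csv: {active.metadata['n_active']} of {motion.n_larvae} larvae "
          f"active at {motion.motion_frequency} Hz, "
          f"peak |V| = {abs(active.samples).max() * 1e3:.3f} mV")

    control = syn.generate_recording(cfg, replace(motion, active_fraction=0.0), noise)
    write_waveform_csv(control, SCRATCH / "control.csv")
    print(f"control.csv: no active larvae, peak |V| = "
          f"{abs(control.samples).max() * 1e3:.4f} mV")

    for drive in (1.0, 2.0, 3.0, 4.0):
        w = syn.generate_driven_recording(
            replace(cfg, seed=args.seed + int(drive)), drive, 1e-4, noise
        )
        write_waveform_csv(w, SCRATCH / f"driven_{drive:.0f}hz.csv")
    print("driven_1hz..driven_4hz.csv: constant-vibration conditions (0.1 mV)")


if __name__ == "__main__":
    main()
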