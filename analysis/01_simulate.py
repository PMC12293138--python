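"""Generate the five synthetic subjects and verify their train/test budgets.

Writes competition-layout matrix files (continuous 0.1 µV integer signal,
cue markers, channel info) to scratch/datasets/ — one per subject — and
prints the per-subject split counts (aa 168/112, al 224/56, av 84/196,
aw 56/224, ay 28/252; 280 trials each).
"""

import sys
from pathlib import Path

import mi_esi as m
from mi_esi.experiment import cli_main

OUT = Path(__file__).resolve().parents[1] / "scratch" / "datasets"
SEED = 0


def main() -> int:
    rc = cli_main(["simulate", "--out", str(OUT), "--seed", str(SEED)])
    if rc != 0:
        return rc
    print("\nround-trip check via the competition-format reader:")
    for subject, (n_train, n_test) in sorted(m.TABLE1_SPLITS.items()):
        rec = m.read_competition_recording(OUT / f"data_{subject}.mat")
        n = len(rec.cue_samples)
        print(f"  {subject}: {n} cues at {rec.fs:g} Hz, "
              f"{len(rec.channel_names)} channels "
              f"(split {n_train} train / {n_test} test)")
        assert n == n_train + n_test == 280
    return 0


if __name__ == "__main__":
    sys.exit(main())
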