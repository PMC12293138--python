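"""Aggregate ablation results and check the published benchmark arithmetic.

Recomputes mean rows from the per-subject rows of results/ablation/ (written
by 02_run_ablation.py) and, independently, verifies the shipped published
benchmark table: its mean linear accuracies per channel count
(83.63 / 84.70 / 84.73 / 83.95) and the F1 = 2*Pre*Sen/(Pre+Sen) identity
for every row.
"""

import sys
from pathlib import Path

from mi_esi.experiment import cli_main

RESULTS = Path(__file__).resolve().parents[1] / "results" / "ablation"


def main() -> int:
    rj = RESULTS / "results.json"
    if rj.exists():
        print("== synthetic ablation summary ==")
        rc = cli_main(["report", "--results", str(rj), "--out", str(RESULTS)])
        if rc != 0:
            return rc
    else:
        print(f"no ablation results at {rj}; run 02_run_ablation.py first")
    print("\n== published benchmark arithmetic ==")
    return cli_main(["verify"])


if __name__ == "__main__":
    sys.exit(main())
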