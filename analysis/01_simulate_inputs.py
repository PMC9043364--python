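#!/usr/bin/env python
"""Generate one synthetic dataset of every input class under results/simulated/:
an ITC titration with its dilution blank, a melting curve, an unassigned
fingerprint pair, hetNOE intensity pairs and a designed indole ring pair.
These are the same dialects the analysis CLI reads, so every later step can
be re-run from these files alone."""

import subprocess
import sys
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main() -> None:
    seed = sys.argv[1] if len(sys.argv) > 1 else "1"
    for kind in ("isotherm", "melt", "fingerprint", "relaxation", "ringpair"):
        dest = OUT / kind
        subprocess.run(
            [sys.executable, "-m", "cwbind.cli", "simulate", kind,
             "--out", str(dest), "--seed", seed],
            check=True,
        )
    print(f"wrote synthetic inputs for 5 stages under {OUT}")


if __name__ == "__main__":
    main()
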