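#!/usr/bin/env python
"""Benchmark the strand cross-correlation filter on planted truth.

Across 20 seeded simulations (20 true sites, 10 phantom stacks, 300
reads/site, background 5e-4 per base per strand) measures the fraction of
true-site peaks retained and phantom peaks rejected at the default
thresholds (shifted >= 0.7, shifted - unshifted >= 0.1).
"""

import json
from pathlib import Path

from mitobook import evaluation as ev

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    out = ev.filter_discrimination(n_seeds=20, base_seed=seed)
    OUT.mkdir(exist_ok=True)
    with open(OUT / "filter_discrimination.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(
        f"true-site retention {out['true_retention']:.3f} "
        f"({out['true_total']} peaks); phantom rejection "
        f"{out['phantom_rejection']:.3f} ({out['phantom_total']} peaks)"
    )


if __name__ == "__main__":
    main()
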