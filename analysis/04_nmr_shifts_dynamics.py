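#!/usr/bin/env python
"""Fingerprint perturbation and backbone dynamics.

Quantifies how much of an amide fingerprint moves for synthetic analogues
of the mutant spectra (designed shifted fractions spanning the little-
perturbed loop mutant to the heavily perturbed helix mutants), and
classifies backbone mobility from synthetic hetNOE profiles with a flexible
loop planted at low NOE.  Writes results/fingerprint_fractions.tsv and
results/hetnoe_classes.tsv."""

from pathlib import Path

import pandas as pd

from cwbind import csp, relax, synth

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for fraction in (0.0, 0.07, 0.45, 0.60):
        ref, qry, labels = synth.gen_fingerprint(
            n_peaks=60, shifted_fraction=fraction, displacement_ppm=0.3,
            jitter_ppm=0.01, seed=1)
        pairing = csp.match_unassigned(ref, qry)
        measured = csp.fraction_shifted(pairing, threshold=0.2)
        rows.append({"designed_fraction_pct": 100 * fraction,
                     "planted_peaks": sum(labels),
                     "measured_pct_gt_0.2ppm": measured,
                     "matched": len(pairing.pairs)})
    frac = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    frac.to_csv(RESULTS / "fingerprint_fractions.tsv", sep="\t", index=False)

    # flexible eta1-like loop at NOE 0.6 on an otherwise ordered backbone
    loop = set(range(20, 26))
    profile = {i: (0.6 if i in loop else 0.82) for i in range(1, 61)}
    records = [relax.het_noe(s, r, id=i)
               for i, s, r in synth.gen_relaxation_noe(profile, noise=0.0)]
    classes = relax.classify_mobility(records, flexible_below=0.75)
    flexible_ids = sorted(r.id for r in classes["flexible"])
    noe = pd.DataFrame([{"id": r.id, "noe": r.noe,
                         "class": "flexible" if r.id in set(flexible_ids) else "ordered"}
                        for r in records])
    noe.to_csv(RESULTS / "hetnoe_classes.tsv", sep="\t", index=False)

    print(frac.to_string(index=False))
    print(f"\nflexible residues recovered: {flexible_ids} "
          f"(planted: {sorted(loop)})")


if __name__ == "__main__":
    main()
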