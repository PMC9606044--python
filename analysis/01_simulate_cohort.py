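#!/usr/bin/env python
"""Stage 1 — generate and persist the synthetic trial cohort.

Builds the digital phantom (atlas, FDG-uptake pattern, GM probability map),
samples the four-arm longitudinal patient series plus the healthy-control
pool, and writes everything under results/cohort/ (NIfTI scans, volumetry
CSV, per-subject ground-truth table).
"""

import argparse
from pathlib import Path

from ambarpet.cohort import CohortSpec, sample_control_scans, sample_patient_series, write_cohort
from ambarpet.phantom import PhantomSpec, build_phantom


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    pspec = PhantomSpec(seed=args.seed)
    cspec = CohortSpec(seed=args.seed)
    phantom = build_phantom(pspec)
    atlas, uptake, _ = phantom

    records, _ = sample_patient_series(pspec, cspec, phantom)
    controls = sample_control_scans(uptake, cspec.n_controls, pspec.noise_sd, seed=args.seed + 1)
    out = write_cohort(records, atlas, controls, args.out)

    n_scans = sum(len(r.scans) for r in records)
    print(f"wrote {len(records)} subjects ({n_scans} scans), "
          f"{len(controls)} controls to {out}")


if __name__ == "__main__":
    main()
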