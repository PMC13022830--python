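#!/usr/bin/env python
"""Tract- and region-wise screening of p-tau181 effects.

Runs main-effect and interaction screens over the 48-tract FA/MD/MO
families and the 124 grey-matter regions, with BH-FDR within each
(family x effect) set.  Writes one tidy TSV per screen and prints the
FDR-surviving members.
"""

import argparse
from pathlib import Path

from vascsynergy import read_cohort, screen_features


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = read_cohort(args.outdir / "cohort_built.tsv")
    for fam in ("tracts_FA", "tracts_MD", "tracts_MO", "gm_regions",
                "gm_first"):
        for effect in ("main", "interaction"):
            t = screen_features(df, fam, effect=effect)
            t.to_csv(args.outdir / f"massuniv_{fam}_{effect}.tsv", sep="\t",
                     index=False, float_format="%.6g")
            hits = t[t.significant]
            print(f"{fam}/{effect}: {len(hits)}/{len(t)} with q < 0.05"
                  + (f" -> {hits.label.tolist()[:6]}" if len(hits) else ""))


if __name__ == "__main__":
    main()
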