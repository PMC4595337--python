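#!/usr/bin/env python
"""Dataset-level statistics: disorder by group, interface composition,
correlations, and the stand-in energy comparison.

Runs the full dataset summary over scratch/dataset/ and writes its tables to
results/analysis/ (disorder_by_*.tsv, enrichment_interface.tsv,
correlations.tsv, energy_comparison.tsv, chains.tsv).
"""

import argparse
from pathlib import Path

from discons.pipeline import PipelineConfig, run_dataset_summary


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=Path("scratch/dataset"))
    parser.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()

    tables = run_dataset_summary(
        sequence_dir=args.data / "sequences",
        structure_dir=args.data / "structures",
        energies_tsv=args.data / "energies.tsv",
        config=PipelineConfig(),
        out_dir=args.out,
    )

    by_class = tables["disorder_by_binding_class"].set_index("binding_class")
    print("mean disorder fraction by binding class:")
    for cls, row in by_class.iterrows():
        print(f"  {cls:10s} {row['mean']:.3f} (n={int(row['n'])})")

    enrich = tables["enrichment_interface"].set_index("amino_acid")
    print(f"interface enrichment: R {enrich.loc['R', 'relative_change']:+.0f}%, "
          f"K {enrich.loc['K', 'relative_change']:+.0f}%")

    for _, row in tables["correlations"].iterrows():
        print(f"  {row['method']:8s} {row['x']} vs {row['y']}: {row['coefficient']:+.3f}")

    if "energy_comparison" in tables:
        for _, row in tables["energy_comparison"].iterrows():
            print(f"  energies {row['group_a']} vs {row['group_b']}: "
                  f"Welch t = {row['statistic']:+.2f}, p = {row['p_value']:.3g}")


if __name__ == "__main__":
    main()
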