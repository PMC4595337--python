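#!/usr/bin/env python
"""Score the planted alignment: SCS, DCS, four-way classification.

Reads scratch/dataset/alignments/ (alignment + the per-residue disorder
scores written alongside it, the same two-input shape as the CLI's
``conserve --msa ... --disorder ...``), writes results/analysis/:
  column_annotations.tsv   per-column scores and categories
  category_counts.tsv      classification counts
  score_pair_matrix.tsv    the 10x10 binned (SCS, DCS) count matrix behind
                           the score-pair heat maps
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from discons.conservation import annotate_msa, category_histogram
from discons.disorder import DisorderProfile
from discons.io_formats import read_alignment
from discons.pipeline import annotations_frame, write_table


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=Path("scratch/dataset"))
    parser.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    msa = read_alignment(args.data / "alignments" / "planted.fasta")
    truth = pd.read_csv(args.data / "alignments" / "planted_truth.tsv", sep="\t")
    scores = pd.read_csv(args.data / "alignments" / "planted_disorder.tsv", sep="\t")
    by_id = {
        rid: DisorderProfile(rid, group.sort_values("position")["score"].to_numpy())
        for rid, group in scores.groupby("id")
    }
    profiles = [by_id[rid] for rid in msa.ids]

    annotations = annotate_msa(msa, profiles)
    table = annotations_frame(annotations)
    write_table(table, args.out / "column_annotations.tsv")

    merged = table.merge(truth, on="column_index", suffixes=("", "_planted"))
    agreement = (merged["category"] == merged["category_planted"]).mean()
    counts, matrix = category_histogram(annotations)
    write_table(pd.DataFrame([counts]), args.out / "category_counts.tsv")
    np.savetxt(args.out / "score_pair_matrix.tsv", matrix, fmt="%d", delimiter="\t")

    print(f"{msa.n_cols} columns classified; category counts: {counts}")
    print(f"agreement with planted truth: {agreement:.2%}")


if __name__ == "__main__":
    main()
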