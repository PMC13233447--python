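"""Worked-example baseline cohort: TCGA endometrial carcinoma stratified at
median SNRPE expression.

The packaged table carries the published per-cell counts of baseline
clinicopathological characteristics for 545 patients (273 low-, 272
high-expression).  Counts that do not sum to the group size reflect
missing values; :func:`expand_to_records` reconstitutes a per-patient
record table from the counts so that the available-case summary machinery
(:func:`splicescreen.survival.clinical_table`) can recompute every
percentage and group test from first principles.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

GROUP_SIZES = {"low": 273, "high": 272}


def load_baseline_counts() -> pd.DataFrame:
    """Packaged per-cell baseline counts (characteristic, level, per group)."""
    ref = resources.files("splicescreen.data") / "ucec_snrpe_baseline.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def expand_to_records(counts: pd.DataFrame | None = None,
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Reconstitute per-patient records from cell counts.

    Within each group and characteristic, the first patients receive the
    levels in table order and any remainder up to the group size is left
    missing.  Characteristics are filled independently, which is exactly
    what available-case analysis assumes.  Returns ``(records, labels)``.
    """
    counts = counts if counts is not None else load_baseline_counts()
    frames = []
    for group, size in GROUP_SIZES.items():
        df = pd.DataFrame(index=pd.Index(
            [f"{group}_{i:03d}" for i in range(size)], name="patient_id"))
        for char, sub in counts.groupby("characteristic", sort=False):
            values: list = []
            for row in sub.itertuples(index=False):
                values += [row.level] * int(getattr(row, f"{group}_n"))
            if len(values) > size:
                raise ValueError(
                    f"{char}: counts exceed group size for {group}")
            values += [np.nan] * (size - len(values))
            df[char] = values
        df["group"] = group
        frames.append(df)
    records = pd.concat(frames)
    labels = records.pop("group")
    return records, labels
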