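from __future__ import annotations

import pandas as pd
import pytest

from edtool import Cohort, MutationRecord


@pytest.fixture
def maf_factory(tmp_path):
    """Write a MAF file from a list of row dicts and return its path."""

    def _write(rows, name="toy.maf", columns=None):
        df = pd.DataFrame(rows)
        if columns is not None:
            df = df[columns]
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write


def make_records(spec):
    """Build MutationRecord objects from (sample, gene, impact_class, ...) tuples."""
    out = []
    for row in spec:
        sample, gene, impact = row[:3]
        extra = row[3] if len(row) > 3 else {}
        out.append(MutationRecord(sample_id=sample, gene=gene, impact_class=impact, **extra))
    return out


@pytest.fixture
def small_cohort():
    """Five samples; gene A mutated (non-silently) in S1, S2; B in S1, S3."""
    records = make_records(
        [
            ("S1", "A", "missense"),
            ("S2", "A", "nonsense"),
            ("S3", "A", "synonymous"),
            ("S1", "B", "missense"),
            ("S3", "B", "missense"),
            ("S4", "B", "synonymous"),
        ]
    )
    return Cohort.from_records(records, roster=["S1", "S2", "S3", "S4", "S5"])
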