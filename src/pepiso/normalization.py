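"""Log2 transform and per-sample median centering of composed group areas.

Median centering removes multiplicative loading/acquisition offsets: after
subtracting each sample's median log2 area (computed over present values
only, the Perseus convention), every sample column has median exactly 0 and
between-sample comparisons of a group are invariant to any per-sample
constant offset introduced upstream.  The even-count median is the mean of
the two central order statistics.  Missing values pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyColumnError
from .io_formats import PeptideKey
from .isoform_mapping import ProteinGroupMatrix


@dataclass
class NormalizedMatrix:
    """Log2, median-centered group-by-sample values plus the offsets removed."""

    values: pd.DataFrame
    meta: pd.DataFrame
    membership: dict[str, list[PeptideKey]]
    sample_medians: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def log2_transform(matrix: ProteinGroupMatrix) -> ProteinGroupMatrix:
    """Elementwise log2 of present areas; missing preserved.

    Zeros must have been mapped to missing upstream; a nonpositive present
    value is a domain error naming the offending cell.
    """
    areas = matrix.areas
    bad = areas.le(0.0)
    if bad.any().any():
        stacked = bad.stack()
        gid, sample = stacked[stacked].index[0]
        raise DomainError(
            f"nonpositive area at group {gid!r}, sample {sample!r}; "
            "map zeros to missing before the log transform"
        )
    return ProteinGroupMatrix(
        np.log2(areas), matrix.meta, matrix.membership, dict(matrix.log)
    )


def median_center(matrix: ProteinGroupMatrix) -> NormalizedMatrix:
    """Subtract each sample's median of present values from its column."""
    values = matrix.areas
    n_present = values.notna().sum(axis=0)
    if (n_present == 0).any():
        empty = list(n_present.index[n_present == 0])
        raise EmptyColumnError(f"sample column(s) with no observed values: {empty}")
    medians = values.median(axis=0, skipna=True)
    centered = values.sub(medians, axis=1)
    return NormalizedMatrix(centered, matrix.meta, matrix.membership, medians)


def normalize(matrix: ProteinGroupMatrix) -> NormalizedMatrix:
    """Convenience: ``median_center(log2_transform(matrix))``."""
    return median_center(log2_transform(matrix))
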