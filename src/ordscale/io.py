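"""Reading and writing the package's CSV interchange formats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .polychoric import PolychoricResult, pair_order
from .synthetic import ItemResponseMatrix

__all__ = ["read_responses", "write_responses", "write_polychoric"]


def read_responses(path, reversal_map=None) -> ItemResponseMatrix:
    """Read a headered CSV of integer item responses.

    ``reversal_map`` lists item labels whose coding should be flipped
    (x -> 3 - x) before analysis, for scales with reverse-keyed items.
    Out-of-range or missing cells raise with the offending row and column.
    """
    df = pd.read_csv(path)
    if df.isna().any().any():
        row, col = next(
            (r, c) for c in df.columns for r in df.index[df[c].isna()]
        )
        raise ValueError(f"missing value at row {row}, column {col!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if np.any(values != np.round(values)):
            bad = np.argwhere(values != np.round(values))[0]
            raise ValueError(
                f"non-integer value at row {bad[0]}, column {df.columns[bad[1]]!r}"
            )
        values = values.astype(np.int64)
    out_of_range = (values < 0) | (values > 3)
    if out_of_range.any():
        bad = np.argwhere(out_of_range)[0]
        raise ValueError(
            f"value {values[bad[0], bad[1]]} out of range {{0..3}} at "
            f"row {bad[0]}, column {df.columns[bad[1]]!r}"
        )
    labels = tuple(df.columns)
    if reversal_map:
        unknown = set(reversal_map) - set(labels)
        if unknown:
            raise ValueError(f"reversal_map names unknown items: {sorted(unknown)}")
        for item in reversal_map:
            j = labels.index(item)
            values[:, j] = 3 - values[:, j]
    return ItemResponseMatrix(values=values, item_labels=labels)


def write_responses(matrix: ItemResponseMatrix, path) -> None:
    matrix.to_frame().to_csv(path, index=False)


def write_polychoric(result: PolychoricResult, r_path, thresholds_path, acov_path=None) -> None:
    """Emit R and thresholds as labelled CSV; acov as a square pair-labelled CSV."""
    labels = list(result.item_labels)
    pd.DataFrame(result.R, index=labels, columns=labels).to_csv(r_path)
    pd.DataFrame(
        result.thresholds.values,
        index=labels,
        columns=[f"tau{k}" for k in (1, 2, 3)],
    ).to_csv(thresholds_path)
    if acov_path is not None and result.acov is not None:
        pair_labels = [
            f"{labels[i]}~{labels[j]}" for i, j in pair_order(len(labels))
        ]
        pd.DataFrame(result.acov, index=pair_labels, columns=pair_labels).to_csv(acov_path)
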