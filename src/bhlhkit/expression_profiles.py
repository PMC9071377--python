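"""FPKM expression matrices and tissue-predominance calling.

Expression values arrive as FPKM (genes x tissues), are log2(FPKM+1)
transformed for reporting, and tissue-predominant expression is called
when a tissue holds the unique row maximum with a configurable linear
fold margin over the runner-up and a minimum expression floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, StateError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x tissues matrix; NaN entries are missing samples."""

    values: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise InputError("expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


def log_transform_matrix(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(FPKM + 1); missing values stay missing."""
    if m.transformed:
        raise StateError("matrix is already log-transformed")
    arr = m.values.to_numpy(dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise InputError("negative FPKM value")
    return ExpressionMatrix(pd.DataFrame(
        np.log2(arr + 1.0), index=m.values.index, columns=m.values.columns
    ), transformed=True)


@dataclass(frozen=True)
class PredominanceCall:
    gene: str
    tissue: str
    max_value: float  # linear FPKM of the row maximum
    second_value: float
    fold_margin: float
    verdict: bool


def call_tissue_predominance(
    m: ExpressionMatrix,
    tissue: str,
    fold_threshold: float = 2.0,
    min_expression: float = 1.0,
) -> list[PredominanceCall]:
    """Per-gene verdict: is ``tissue`` the predominant expression site?

    The verdict is true iff the tissue attains the unique row maximum,
    the maximum is at least ``min_expression`` FPKM, and exceeds the
    runner-up by ``fold_threshold`` on the linear scale.  Rows that are
    entirely missing are skipped with a warning.
    """
    if tissue not in m.values.columns:
        raise InputError(f"unknown tissue {tissue!r}")
    if not m.transformed:
        raise StateError("predominance calling expects a log-transformed matrix")
    calls: list[PredominanceCall] = []
    linear = np.power(2.0, m.values.to_numpy(dtype=float)) - 1.0
    frame = pd.DataFrame(linear, index=m.values.index, columns=m.values.columns)
    for gene, row in frame.iterrows():
        present = row.dropna()
        if present.empty:
            logger.warning("gene %s has no expression values; skipped", gene)
            continue
        ordered = present.sort_values(ascending=False)
        max_value = float(ordered.iloc[0])
        second_value = float(ordered.iloc[1]) if len(ordered) > 1 else 0.0
        unique_max = (
            tissue in present.index
            and present[tissue] == max_value
            and (present == max_value).sum() == 1
        )
        fold_margin = max_value / second_value if second_value > 0 else float("inf")
        verdict = bool(
            unique_max
            and max_value >= min_expression
            and max_value >= fold_threshold * second_value
        )
        calls.append(PredominanceCall(
            gene=str(gene), tissue=tissue, max_value=max_value,
            second_value=second_value, fold_margin=fold_margin, verdict=verdict,
        ))
    return calls
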