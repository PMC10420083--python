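"""Classification accuracy assessment from a 2x2 confusion matrix.

The rapeseed-extraction map is scored against visually interpreted reference
pixels.  Rows are the mapped class, columns the reference class, order
(NOR, OR) = (non-rapeseed, rapeseed).  Metrics: overall accuracy (OA), user
accuracy per mapped class (UA, row-wise), producer accuracy per reference
class (PA, column-wise), and Cohen's kappa with chance agreement
p_e = sum_c row_c * col_c / total^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix2:
    """2x2 confusion counts; rows = mapped class, columns = reference class."""

    counts: np.ndarray
    labels: tuple[str, str] = ("NOR", "OR")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("confusion matrix is empty")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix2":
        """CSV with header = reference labels and index column = mapped labels."""
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), labels=tuple(str(c) for c in df.columns))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConfusionMatrix2":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["counts"]), labels=tuple(d.get("labels", ("NOR", "OR"))))


def confusion_metrics(m: ConfusionMatrix2) -> dict:
    """OA/UA/PA (percent) and kappa at full precision.

    A zero row or column sum makes the affected UA/PA NaN ("undefined");
    every other metric is still computed.  Use :func:`format_report` for the
    2-decimal presentation.
    """
    c = m.counts.astype(float)
    total = c.sum()
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    diag = np.diag(c)
    p_o = diag.sum() / total
    with np.errstate(divide="ignore", invalid="ignore"):
        ua = np.where(row > 0, diag / row, np.nan)
        pa = np.where(col > 0, diag / col, np.nan)
    p_e = float(np.sum(row * col) / total**2)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e != 1.0 else float("nan")
    return {
        "OA": 100.0 * p_o,
        "UA": {m.labels[i]: 100.0 * ua[i] for i in range(2)},
        "PA": {m.labels[i]: 100.0 * pa[i] for i in range(2)},
        "kappa": float(kappa),
    }


def format_report(metrics: dict) -> str:
    """Render metrics with the conventional 2-decimal display rounding."""
    lines = [f"OA (%)    {metrics['OA']:.2f}"]
    for cls, v in metrics["UA"].items():
        lines.append(f"UA {cls} (%)  {v:.2f}" if np.isfinite(v) else f"UA {cls} (%)  undefined")
    for cls, v in metrics["PA"].items():
        lines.append(f"PA {cls} (%)  {v:.2f}" if np.isfinite(v) else f"PA {cls} (%)  undefined")
    lines.append(f"Kappa     {metrics['kappa']:.2f}")
    return "\n".join(lines)
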