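"""Evaluation metrics for thickness estimates at patch and B-scan level.

The triad is MAE (mean |error|), ME (mean signed error — negative means the
model underestimates thickness) and the Pearson correlation between
predictions and ground truth, each with the population SD of the underlying
per-sample errors.  Interval tables report the fraction of samples whose
absolute error falls in <=5, (5, 10], (10, 15] and >15 pixels.

Because every B-scan contributes the same number K of equal-width patches,
the B-scan signed errors are the group means of the patch signed errors, so
ME is identical at both levels, while MAE at B-scan level is never larger
than at patch level (averaging lets over- and under-estimates cancel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PredictionRecord

__all__ = [
    "EvalReport",
    "mae",
    "me",
    "pcc",
    "aggregate_to_bscan",
    "interval_table",
    "scatter_export",
    "evaluate_records",
]

DEFAULT_INTERVAL_BOUNDS = (5.0, 10.0, 15.0)


def _errors(records: Sequence[PredictionRecord]) -> np.ndarray:
    if not records:
        raise ValueError("no prediction records given")
    return np.array([r.predicted - r.truth for r in records], dtype=float)


def mae(records: Sequence[PredictionRecord]) -> tuple[float, float]:
    """Mean and population SD of the absolute errors |f_s - y_s|."""
    ae = np.abs(_errors(records))
    return float(ae.mean()), float(ae.std())


def me(records: Sequence[PredictionRecord]) -> tuple[float, float]:
    """Mean and population SD of the signed errors f_s - y_s."""
    err = _errors(records)
    return float(err.mean()), float(err.std())


def pcc(records: Sequence[PredictionRecord]) -> float:
    """Pearson correlation between predictions and ground truth."""
    if len(records) < 2:
        raise ValueError("Pearson correlation needs at least 2 records")
    f = np.array([r.predicted for r in records], dtype=float)
    y = np.array([r.truth for r in records], dtype=float)
    if f.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined: zero variance")
    return float(np.corrcoef(f, y)[0, 1])


def aggregate_to_bscan(patch_records: Sequence[PredictionRecord],
                       expected_patches: int | None = None) -> list[PredictionRecord]:
    """Collapse patch records to one record per B-scan.

    Per B-scan (subject, volume, slice) the prediction is the mean of the
    patch predictions and the truth the mean of the patch truths.  Every
    group must be complete: either ``expected_patches`` members, or — when
    not given — the same count for all B-scans.
    """
    groups: dict[tuple, list[PredictionRecord]] = {}
    for r in patch_records:
        groups.setdefault((r.subject_id, r.volume_id, r.slice_index), []).append(r)
    sizes = {len(v) for v in groups.values()}
    k = expected_patches if expected_patches is not None else max(sizes)
    for key, members in groups.items():
        if len(members) != k:
            raise ValueError(
                f"B-scan {key} has {len(members)} patches, expected {k}"
            )
    out = []
    for (subject, volume, slice_index), members in groups.items():
        out.append(PredictionRecord(
            level="bscan", subject_id=subject, volume_id=volume,
            slice_index=slice_index, segment_index=None,
            predicted=float(np.mean([m.predicted for m in members])),
            truth=float(np.mean([m.truth for m in members])),
        ))
    return out


def interval_table(records: Sequence[PredictionRecord],
                   bounds: Sequence[float] = DEFAULT_INTERVAL_BOUNDS) -> np.ndarray:
    """Fractions of records with AE <= b1, (b1, b2], (b2, b3], > b3.

    The first bin is closed on the right (AE exactly at the first bound
    counts as "small error"); fractions sum to 1.
    """
    ae = np.abs(_errors(records))
    b1, b2, b3 = bounds
    counts = np.array([
        np.count_nonzero(ae <= b1),
        np.count_nonzero((ae > b1) & (ae <= b2)),
        np.count_nonzero((ae > b2) & (ae <= b3)),
        np.count_nonzero(ae > b3),
    ], dtype=float)
    return counts / len(ae)


def scatter_export(records: Sequence[PredictionRecord],
                   csv_path: str | Path | None = None,
                   figure_path: str | Path | None = None) -> pd.DataFrame:
    """(truth, prediction) table for agreement scatterplots.

    Optionally writes the table to CSV and renders a scatterplot with the
    identity line (points on the line are perfect predictions).
    """
    if not records:
        raise ValueError("no prediction records given")
    df = pd.DataFrame({
        "truth": [r.truth for r in records],
        "prediction": [r.predicted for r in records],
    })
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(df["truth"], df["prediction"], s=6, alpha=0.5)
        lo = min(df.min()) - 2
        hi = max(df.max()) + 2
        ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="identity")
        ax.set_xlabel("ground truth (pixels)")
        ax.set_ylabel("prediction (pixels)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return df


@dataclass
class EvalReport:
    """MAE/ME (+/- SD), Pearson correlation and AE-interval fractions."""

    level: str
    mae: float
    mae_sd: float
    me: float
    me_sd: float
    pcc: float
    interval_percentages: tuple[float, float, float, float]
    n_samples: int
    interval_bounds: tuple[float, float, float] = DEFAULT_INTERVAL_BOUNDS
    sd_convention: str = "population"

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "mae": self.mae,
            "mae_sd": self.mae_sd,
            "me": self.me,
            "me_sd": self.me_sd,
            "pcc": self.pcc,
            "interval_bounds": list(self.interval_bounds),
            "interval_percentages": list(self.interval_percentages),
            "n_samples": self.n_samples,
            "sd_convention": self.sd_convention,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_markdown(self) -> str:
        b1, b2, b3 = self.interval_bounds
        p = self.interval_percentages
        lines = [
            f"| metric | value ({self.level} level, n={self.n_samples}) |",
            "|---|---|",
            f"| MAE (px) | {self.mae:.4f} +/- {self.mae_sd:.4f} |",
            f"| ME (px) | {self.me:.4f} +/- {self.me_sd:.4f} |",
            f"| PCC | {self.pcc:.4f} |",
            f"| AE <= {b1:g} | {p[0]:.2%} |",
            f"| {b1:g} < AE <= {b2:g} | {p[1]:.2%} |",
            f"| {b2:g} < AE <= {b3:g} | {p[2]:.2%} |",
            f"| AE > {b3:g} | {p[3]:.2%} |",
        ]
        return "\n".join(lines)


def evaluate_records(records: Sequence[PredictionRecord], level: str) -> EvalReport:
    """Assemble the full report for one level ("patch" or "bscan")."""
    mae_v, mae_sd = mae(records)
    me_v, me_sd = me(records)
    fractions = interval_table(records)
    return EvalReport(
        level=level, mae=mae_v, mae_sd=mae_sd, me=me_v, me_sd=me_sd,
        pcc=pcc(records), interval_percentages=tuple(float(f) for f in fractions),
        n_samples=len(records),
    )
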