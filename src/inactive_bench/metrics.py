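"""Confusion-matrix metrics and the evaluation grid.

Metrics are recall R = TP/(TP+FN), precision P = TP/(TP+FP) and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with "active" the positive class.  A zero denominator does not abort a grid
run: the metric is reported as 0.0 with an ``undefined`` flag, so degenerate
classifiers (always-inactive, always-active) remain comparable rows.

The grid is a long-format table indexed by classifier x inactive source x
fingerprint x mode x iteration; aggregation gives the arithmetic mean and
the sample (n-1) standard deviation over iterations or over sources, with
undefined cells excluded and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

METRIC_NAMES = ("recall", "precision", "mcc")

GRID_COLUMNS = ["classifier", "source", "fingerprint", "mode", "iteration",
                "metric", "value", "undefined"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsResult:
    recall: float
    precision: float
    mcc: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {"recall": self.recall, "precision": self.precision, "mcc": self.mcc}


def confusion(predictions: Iterable, truth: Iterable) -> ConfusionCounts:
    """Tally a confusion matrix; accepts bool arrays or 'active'/'inactive' labels."""

    def to_bool(seq) -> np.ndarray:
        arr = np.asarray(list(seq) if not isinstance(seq, np.ndarray) else seq)
        if arr.dtype.kind in "bi":
            return arr.astype(bool)
        return np.array([str(v).lower() == "active" for v in arr])

    pred, true = to_bool(predictions), to_bool(truth)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    return ConfusionCounts(
        tp=int((pred & true).sum()),
        fp=int((pred & ~true).sum()),
        tn=int((~pred & ~true).sum()),
        fn=int((~pred & true).sum()),
    )


def compute_metrics(cc: ConfusionCounts) -> MetricsResult:
    """Recall, precision and MCC; zero denominators flagged as undefined."""
    undefined: set[str] = set()
    recall = precision = mcc = 0.0
    if cc.tp + cc.fn > 0:
        recall = cc.tp / (cc.tp + cc.fn)
    else:
        undefined.add("recall")
    if cc.tp + cc.fp > 0:
        precision = cc.tp / (cc.tp + cc.fp)
    else:
        undefined.add("precision")
    denom = ((cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn))
    if denom > 0:
        mcc = (cc.tp * cc.tn - cc.fp * cc.fn) / math.sqrt(denom)
    else:
        undefined.add("mcc")
    return MetricsResult(recall=recall, precision=precision, mcc=mcc,
                         undefined=frozenset(undefined))


@dataclass
class EvaluationGrid:
    """Long-format metric table plus aggregation and TSV export."""

    rows: list[dict] = field(default_factory=list)

    def add(self, classifier: str, source: str, fingerprint: str, mode: str,
            iteration: int, result: MetricsResult) -> None:
        for metric in METRIC_NAMES:
            self.rows.append({
                "classifier": classifier, "source": source,
                "fingerprint": fingerprint, "mode": mode,
                "iteration": str(iteration), "metric": metric,
                "value": float(getattr(result, metric)),
                "undefined": metric in result.undefined,
            })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=GRID_COLUMNS)

    def aggregate(self, axis: Literal["iterations", "sources"] = "iterations"
                  ) -> pd.DataFrame:
        """Mean and sample SD over the chosen axis, per remaining index group.

        Undefined cells are excluded from the statistics; ``n_undefined``
        reports how many were dropped.  SD is present only for groups with at
        least two defined values.
        """
        frame = self.to_frame()
        if frame.empty:
            raise ValueError("cannot aggregate an empty grid")
        if axis == "iterations":
            keys = ["classifier", "source", "fingerprint", "mode", "metric"]
        elif axis == "sources":
            keys = ["classifier", "fingerprint", "mode", "metric"]
        else:
            raise ValueError(f"unknown aggregation axis {axis!r}")
        out = []
        for group_key, grp in frame.groupby(keys, sort=True):
            defined = grp.loc[~grp["undefined"], "value"]
            row = dict(zip(keys, group_key))
            row["n"] = len(defined)
            row["n_undefined"] = int(grp["undefined"].sum())
            # a group where every cell is undefined stays in the table as an
            # undefined aggregate (degenerate classifiers must not abort runs)
            row["mean"] = float(defined.mean()) if len(defined) else float("nan")
            row["sd"] = float(defined.std(ddof=1)) if len(defined) >= 2 else float("nan")
            out.append(row)
        return pd.DataFrame(out)

    def export(self, path: str | Path, aggregates: bool = True) -> None:
        """Write the grid as TSV: one row per cell, aggregate rows appended.

        Aggregate rows carry ``iteration = mean|sd`` (over iterations).
        Column order is :data:`GRID_COLUMNS`, stable across exports.
        """
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame().copy()
        if aggregates and not frame.empty:
            agg = self.aggregate(axis="iterations")
            extra = []
            for _, row in agg.iterrows():
                for stat in ("mean", "sd"):
                    value = row[stat]
                    if math.isnan(value):
                        continue
                    extra.append({
                        "classifier": row["classifier"], "source": row["source"],
                        "fingerprint": row["fingerprint"], "mode": row["mode"],
                        "iteration": stat, "metric": row["metric"],
                        "value": float(value), "undefined": False,
                    })
            frame = pd.concat([frame, pd.DataFrame(extra, columns=GRID_COLUMNS)],
                              ignore_index=True)
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_grid(path: str | Path) -> pd.DataFrame:
    """Read back an exported grid TSV (iteration stays a string column)."""
    return pd.read_csv(path, sep="\t", dtype={"iteration": str})


def heatmap(grid: EvaluationGrid, path: str | Path, mode: Optional[str] = None) -> None:
    """Optional graphic twin of the grid: metric heat maps, classifiers x sources."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = grid.to_frame()
    if mode is not None:
        frame = frame[frame["mode"] == mode]
    agg = frame.groupby(["classifier", "source", "metric"])["value"].mean().reset_index()
    metrics = [m for m in METRIC_NAMES if m in set(agg["metric"])]
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3),
                             squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        pivot = agg[agg["metric"] == metric].pivot(
            index="classifier", columns="source", values="value")
        im = ax.imshow(pivot.to_numpy(), vmin=-1 if metric == "mcc" else 0, vmax=1,
                       cmap="RdYlBu_r", aspect="auto")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45,
                      ha="right", fontsize=7)
        ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=7)
        ax.set_title(metric)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
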