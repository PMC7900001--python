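"""Pipeline orchestration: performance grids, sample-size planning, reports.

`run_validation_grid` fits a separate model per outcome and model
timepoint (9 labels: 2, 3, 5, 9, 14, 14*, 15, 17, 17*) and fills two
grids: LOOCV-optimism-corrected R² for continuous outcomes, bootstrap-
corrected c-statistics for ordinal outcomes.  `riley_min_r2` computes the
minimum R² a planned model should have to keep expected shrinkage above a
target, given sample size and predictor count.  `render_reports` writes
CSV tables and matplotlib figures, including the test-retest ICC ceiling
lines (rendered at R² = ICC²: measurement unreliability attenuates the
predictable variance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .linear import loocv_corrected_r2
from .ordinal import bootstrap_corrected_c
from .preprocess import TIMEPOINT_LABELS, assemble_predictors

log = logging.getLogger(__name__)

__all__ = ["PerformanceGrid", "RileyCriterion", "run_validation_grid",
           "riley_min_r2", "render_reports"]


@dataclass
class PerformanceGrid:
    values: pd.DataFrame        # outcomes x timepoint labels
    n: pd.DataFrame             # per-cell rows used
    kind: str                   # "continuous" | "ordinal"
    method: str
    seed: int

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "outcome"
        out.to_csv(path, float_format="%.6g")


@dataclass
class RileyCriterion:
    """Minimum-R² planning criterion from a target shrinkage factor S.

    Solves n = p / ((S - 1) * ln(1 - R²/S)) for R², i.e. the smallest
    anticipated R² for which a model with p predictors fit on n rows keeps
    its expected uniform shrinkage above S (default 0.9).
    """

    n: int
    p: int
    shrinkage: float = 0.9
    variant: str = "shrinkage_factor"

    def validate(self) -> None:
        if not (self.n > self.p >= 1):
            raise ValueError("need n > p >= 1")
        if not 0.0 < self.shrinkage < 1.0:
            raise ValueError("shrinkage target must be in (0, 1)")


def riley_min_r2(criterion: RileyCriterion) -> float:
    """Closed-form solution: R² = S * (1 - exp(p / (n * (S - 1))))."""
    criterion.validate()
    n, p, S = criterion.n, criterion.p, criterion.shrinkage
    r2 = S * (1.0 - np.exp(p / (n * (S - 1.0))))
    if not 0.0 < r2 < 1.0:
        raise ValueError(f"criterion has no solution in (0, 1): {r2}")
    return float(r2)


def run_validation_grid(table, specs: dict, continuous_outcomes: list,
                        ordinal_outcomes: list, seed: int = 0,
                        method: str = "lasso", nested: bool = True,
                        n_lambda: int = 100, n_boot: int = 40):
    """Corrected-performance grids over all outcomes and timepoints.

    ``table`` must have complete (imputed) predictors; rows missing an
    outcome are dropped for that outcome only.  A failed cell is recorded
    as NaN with a logged diagnostic.  Fully seeded: the bootstrap seed for
    each ordinal cell is derived from (seed, outcome, label) so results
    are reproducible cell-by-cell.
    """
    labels = [lb for lb in TIMEPOINT_LABELS if lb in specs]
    cont = pd.DataFrame(np.nan, index=continuous_outcomes, columns=labels)
    cont_n = pd.DataFrame(0, index=continuous_outcomes, columns=labels)
    ord_ = pd.DataFrame(np.nan, index=ordinal_outcomes, columns=labels)
    ord_n = pd.DataFrame(0, index=ordinal_outcomes, columns=labels)

    for lb in labels:
        for out in continuous_outcomes:
            am = assemble_predictors(table, specs[lb], outcome=out)
            mask = ~am.y.isna().to_numpy()
            X = am.X.to_numpy(dtype=float)[mask]
            y = am.y.to_numpy(dtype=float)[mask]
            cont_n.loc[out, lb] = int(mask.sum())
            try:
                perf = loocv_corrected_r2(X, y, method=method, outcome=out,
                                          timepoint_label=lb, nested=nested,
                                          n_lambda=n_lambda)
                cont.loc[out, lb] = perf.r2_corrected
            except (ValueError, np.linalg.LinAlgError) as exc:
                log.warning("cell (%s, %s) failed: %s", out, lb, exc)
        for oi, out in enumerate(ordinal_outcomes):
            am = assemble_predictors(table, specs[lb], outcome=out)
            mask = ~am.y.isna().to_numpy()
            X = am.X.to_numpy(dtype=float)[mask]
            y = am.y.to_numpy()[mask]
            ord_n.loc[out, lb] = int(mask.sum())
            cell_seed = (seed * 1_000_003 + oi * 1009
                         + labels.index(lb)) % (2 ** 31)
            try:
                res = bootstrap_corrected_c(X, y, n_boot=n_boot,
                                            seed=cell_seed, outcome=out,
                                            timepoint_label=lb)
                ord_.loc[out, lb] = res.c_corrected
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                log.warning("cell (%s, %s) failed: %s", out, lb, exc)

    grid_c = PerformanceGrid(values=cont, n=cont_n, kind="continuous",
                             method=method, seed=seed)
    grid_o = PerformanceGrid(values=ord_, n=ord_n, kind="ordinal",
                             method="propodds", seed=seed)
    return grid_c, grid_o


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def icc_ceiling(icc: float) -> float:
    """Upper bound on predictive R² for an outcome with test-retest ICC.

    Only the reliable share of outcome variance is predictable, and a
    predictor built from one error-prone administration is itself
    attenuated, so the ceiling is rendered as ICC².
    """
    return float(icc) ** 2


def render_reports(grids, predictions, out_dir,
                   icc_values=(0.95, 0.8, 0.7), fmt: str = "png") -> list:
    """Write CSV tables and figures; returns the list of files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    for grid in grids:
        path = out_dir / f"performance_{grid.kind}.csv"
        grid.to_csv(path)
        written.append(path)
        fig_path = out_dir / f"performance_{grid.kind}.{fmt}"
        fig, ax = plt.subplots(figsize=(7, 4.5))
        xs = np.arange(len(grid.values.columns))
        for out in grid.values.index:
            ax.plot(xs, grid.values.loc[out].to_numpy(), marker="o",
                    label=out, lw=1)
        if grid.kind == "continuous":
            for icc in icc_values:
                ax.axhline(icc_ceiling(icc), ls="--", color="grey", lw=0.8)
                ax.annotate(f"ICC {icc}", (len(xs) - 1, icc_ceiling(icc)),
                            fontsize=7, color="grey")
            ax.set_ylabel("optimism-corrected R²")
        else:
            ax.set_ylabel("optimism-corrected c-statistic")
        ax.set_xticks(xs, grid.values.columns)
        ax.set_xlabel("model timepoint (age)")
        if 0 < len(grid.values.index) <= 14:
            ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        written.append(fig_path)

    if predictions:
        rows = []
        for name, pred in predictions:
            rows.append({
                "name": name,
                "outcome": pred.outcome or "",
                "point": pred.point, "se_pred": pred.se_pred,
                "lo": pred.interval[0], "hi": pred.interval[1],
                "level": pred.level,
            })
        pred_df = pd.DataFrame(rows)
        path = out_dir / "predictions.csv"
        pred_df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)

        fig, ax = plt.subplots(figsize=(6, 0.45 * len(rows) + 1.2))
        ys = np.arange(len(rows))[::-1]
        for yy, row in zip(ys, rows):
            ax.plot([row["lo"], row["hi"]], [yy, yy], color="C0")
            ax.plot(row["point"], yy, "o", color="C0")
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(ys, [r["name"] for r in rows], fontsize=7)
        ax.set_xlabel("standardized outcome (higher = less severe impact)")
        fig.tight_layout()
        fig_path = out_dir / f"predictions.{fmt}"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        written.append(fig_path)
    else:
        # still write a header-only predictions table for pipeline symmetry
        path = out_dir / "predictions.csv"
        pd.DataFrame(columns=["name", "outcome", "point", "se_pred",
                              "lo", "hi", "level"]).to_csv(path, index=False)
        written.append(path)
    return [str(p) for p in written]
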