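"""Grid search over preprocessing strategy x spectral subrange x map size.

For every combination the full pipeline runs end to end: preprocess on the
shared full grid (calibration-fitted state applied to validation), extract
the modeling subranges, PCA with the cumulative-variance rule, then CP-ANN
training and scoring.  Each grid row reports

* CAC  — per-spectrum classification accuracy on the calibration set,
* CACV — sample-grouped cross-validation accuracy,
* CAV  — per-spectrum accuracy on the held-out validation set,

or an NA flag when the PCA variance rule is unreachable at the component cap
(those strategies wash the class signal into many small components).

The winner is ranked by (CAV, CAC) descending — validation accuracy is the
generalization claim — with ties broken by higher CACV, smaller map, fewer
components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import cpann, pca
from .errors import NoModelError, ParameterError
from .preprocess import PreprocessStrategy
from .spectra_io import Label, SpectraSet, SubrangeSpec, extract_subranges

#: The preprocessing strategies of the published comparison grid.
STANDARD_STRATEGIES = (
    "MC",
    "MSC+MC",
    "SNV+MC",
    "FD+MC",
    "SD+MC",
    "SGS+MC",
    "SGS+FD+MC",
    "NDS+FD+MC",
    "MSC+SD+MC",
    "SNV+NDS+FD+MC",
)

CLASSES = (Label.MUTANT, Label.WILD_TYPE)


@dataclass
class ModelPerformance:
    cac_pct: float
    cacv_pct: float
    cav_pct: float


@dataclass
class GridRow:
    strategy: str
    subrange: str
    n_pcs: int
    cumvar_pct: float
    map_side: int
    performance: ModelPerformance | None  # None = NA (PCA rule unreachable)

    @property
    def is_na(self) -> bool:
        return self.performance is None


@dataclass
class FittedPipeline:
    """Everything needed to re-apply a fitted configuration to new spectra."""

    strategy: PreprocessStrategy
    subrange: SubrangeSpec
    pca_model: pca.PCAModel
    cpann_model: cpann.CPANNModel
    cal_scores: "object" = None
    val_scores: "object" = None


def _subrange_label(spec: SubrangeSpec) -> str:
    return ", ".join(f"{h:g}-{lo:g}" for h, lo in spec.intervals)


def evaluate_config(
    cal: SpectraSet,
    val: SpectraSet | None,
    strategy: PreprocessStrategy | str,
    subrange: SubrangeSpec,
    map_side: int,
    *,
    pca_threshold: float = pca.PCA_VARIANCE_THRESHOLD_PCT,
    pca_cap: int = pca.PCA_COMPONENT_CAP,
    epochs: int = cpann.DEFAULT_EPOCHS,
    lr_start: float = cpann.DEFAULT_LR_START,
    lr_end: float = cpann.DEFAULT_LR_END,
    cv_folds: int | None = 5,
    seed: int = 0,
) -> tuple[GridRow, FittedPipeline | None]:
    """Run one pipeline configuration end to end.

    Returns the grid row and, unless the PCA rule failed (NA row), the fitted
    pipeline artifacts.  ``cv_folds=None`` skips cross-validation (CACV NaN).
    """
    if isinstance(strategy, str):
        strategy = PreprocessStrategy.parse(strategy)

    cal_t, fitted = strategy.fit(cal.absorbance, cal.grid)
    val_t = fitted.apply(val.absorbance, val.grid) if val is not None else None

    cal_sub = extract_subranges(SpectraSet(cal.grid, cal_t, list(cal.meta)), subrange)
    val_sub = (
        extract_subranges(SpectraSet(val.grid, val_t, list(val.meta)), subrange)
        if val is not None
        else None
    )

    pca_model = pca.select_n_pcs(
        pca.fit_pca(cal_sub.absorbance, k_max=pca_cap),
        threshold_pct=pca_threshold,
        cap=pca_cap,
    )
    cumvar = float(pca_model.cumulative_ratio[pca_model.k_selected - 1])
    if not pca_model.valid:
        row = GridRow(
            strategy=str(strategy),
            subrange=_subrange_label(subrange),
            n_pcs=pca_model.k_selected,
            cumvar_pct=cumvar,
            map_side=map_side,
            performance=None,
        )
        return row, None

    cal_scores = pca.project(pca_model, cal_sub.absorbance)
    model = cpann.init_map(map_side, cal_scores.shape[1], len(CLASSES), seed=seed)
    model = cpann.train(
        model,
        cal_scores,
        cpann.one_hot(cal.labels, CLASSES),
        epochs=epochs,
        lr_start=lr_start,
        lr_end=lr_end,
        classes=CLASSES,
    )
    cac = cpann.accuracy_pct(model, cal_scores, cal.labels)

    cacv = float("nan")
    if cv_folds is not None:
        cacv = cpann.cross_validate(
            cal_scores,
            cal.labels,
            cal.meta,
            folds=cv_folds,
            size=map_side,
            epochs=epochs,
            lr_start=lr_start,
            lr_end=lr_end,
            seed=seed,
        )

    val_scores = None
    cav = float("nan")
    if val_sub is not None:
        val_scores = pca.project(pca_model, val_sub.absorbance)
        cav = cpann.accuracy_pct(model, val_scores, val.labels)

    row = GridRow(
        strategy=str(strategy),
        subrange=_subrange_label(subrange),
        n_pcs=pca_model.k_selected,
        cumvar_pct=cumvar,
        map_side=map_side,
        performance=ModelPerformance(cac_pct=cac, cacv_pct=cacv, cav_pct=cav),
    )
    artifacts = FittedPipeline(
        strategy=fitted,
        subrange=subrange,
        pca_model=pca_model,
        cpann_model=model,
        cal_scores=cal_scores,
        val_scores=val_scores,
    )
    return row, artifacts


def run_grid(
    cal: SpectraSet,
    val: SpectraSet,
    strategies: Sequence[PreprocessStrategy | str],
    subranges: Sequence[SubrangeSpec],
    sides: Sequence[int] = cpann.MAP_SIDES,
    seed: int = 0,
    **kwargs,
) -> list[GridRow]:
    """Evaluate every strategy x subrange x map-side combination.

    One shared seed across the grid so rows differ only by configuration.
    """
    if not strategies:
        raise ParameterError("strategy list must not be empty")
    if not subranges:
        raise ParameterError("subrange list must not be empty")
    if cal.grid.values.shape != val.grid.values.shape or (
        cal.grid.values != val.grid.values
    ).any():
        raise ParameterError("calibration and validation sets must share a grid")
    labels = {l for l in cal.labels}
    if not {Label.MUTANT, Label.WILD_TYPE} <= labels:
        raise ParameterError("calibration set must contain both classes")
    rows = []
    for strategy in strategies:
        for subrange in subranges:
            for side in sides:
                row, _ = evaluate_config(
                    cal, val, strategy, subrange, side, seed=seed, **kwargs
                )
                rows.append(row)
    return rows


def select_best(rows: Sequence[GridRow]) -> GridRow:
    """Winner by (CAV, CAC) desc, then CACV desc, smaller map, fewer PCs."""
    candidates = [r for r in rows if not r.is_na]
    if not candidates:
        raise NoModelError("every grid row is NA; no usable model")

    def key(r: GridRow):
        p = r.performance
        cacv = -1.0 if p.cacv_pct != p.cacv_pct else p.cacv_pct  # NaN-safe
        return (p.cav_pct, p.cac_pct, cacv, -r.map_side, -r.n_pcs)

    return max(candidates, key=key)


def grid_to_frame(rows: Sequence[GridRow]) -> pd.DataFrame:
    """Tabular view of the grid, mirroring the published comparison columns."""
    records = []
    for r in rows:
        records.append(
            {
                "preprocessing": r.strategy,
                "subrange_cm-1": r.subrange,
                "n_pcs": r.n_pcs,
                "cumvar_pct": round(r.cumvar_pct, 1),
                "map_side": r.map_side,
                "cac_pct": None if r.is_na else round(r.performance.cac_pct, 1),
                "cacv_pct": None if r.is_na else round(r.performance.cacv_pct, 1),
                "cav_pct": None if r.is_na else round(r.performance.cav_pct, 1),
            }
        )
    return pd.DataFrame.from_records(records)
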