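"""Flow-cytometry gating and developmental-kinetics summaries.

The gating scheme mirrors the study design for the ID4-eGFP / tdTomato
reporter system: germ cells are gated as tdTomato+ against an unstained
control, the eGFP+ signal range of each sample is divided into three
equal-width thirds (on log10 scale by default) to define Bright, Mid and
Dim subsets, DNA-content histograms yield G0/G1 versus S/G2/M fractions,
and per-age subset counts are assembled into a kinetics table with
fold-changes and plateau detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "GateResult",
    "gate_tdtomato",
    "split_egfp_tertiles",
    "cell_cycle_fractions",
    "kit_composition",
    "kinetics_table",
]

SUBSET_ORDER = ("Bright", "Mid", "Dim", "eGFPneg")


@dataclass
class GateResult:
    """Per-event subset labels plus the gate boundaries that produced them.

    ``labels`` is indexed like the gated germ-event table, with values in
    {Bright, Mid, Dim, eGFPneg}.  ``tertile_cutpoints`` are the two interior
    boundaries of the eGFP+ range (intensity units, not log units).
    """

    labels: pd.Series
    tdtomato_threshold: float | None
    egfp_threshold: float
    tertile_cutpoints: tuple[float, float]
    scale: Literal["log", "linear"] = "log"
    empty_tertiles: tuple[str, ...] = ()

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(SUBSET_ORDER, fill_value=0)


def gate_tdtomato(
    events: pd.DataFrame,
    control: pd.DataFrame,
    quantile: float = 0.995,
    column: str = "tdTomato",
) -> tuple[pd.DataFrame, float]:
    """Gate germ cells as events above the control background.

    The threshold is a high quantile (default 99.5th percentile) of the
    unstained-control tdTomato signal; events strictly above it are called
    germ.  Returns the germ subset of ``events`` and the threshold used.
    """
    if len(control) == 0:
        raise ValueError("unstained control table is empty")
    threshold = float(np.quantile(control[column].to_numpy(), quantile))
    germ = events[events[column] > threshold]
    return germ, threshold


def split_egfp_tertiles(
    germ_events: pd.DataFrame,
    egfp_positive_threshold: float,
    column: str = "eGFP",
    scale: Literal["log", "linear"] = "log",
    tdtomato_threshold: float | None = None,
) -> GateResult:
    """Divide each sample's eGFP+ signal range into equal thirds.

    The range from the positivity threshold to the sample maximum is split
    into three equal-width bins (on log10 scale by default, since cytometry
    intensities span decades): Dim, Mid, Bright from low to high.  Events
    below the threshold are eGFP-.  A value exactly at a cutpoint falls in
    the higher bin.
    """
    if egfp_positive_threshold <= 0:
        raise ValueError("eGFP positivity threshold must be positive")
    x = germ_events[column].to_numpy(dtype=float)
    pos = x >= egfp_positive_threshold
    labels = pd.Series("eGFPneg", index=germ_events.index, dtype=object)
    if not pos.any():
        return GateResult(
            labels=labels,
            tdtomato_threshold=tdtomato_threshold,
            egfp_threshold=egfp_positive_threshold,
            tertile_cutpoints=(np.nan, np.nan),
            scale=scale,
            empty_tertiles=("Dim", "Mid", "Bright"),
        )
    if scale == "log":
        lo, hi = np.log10(egfp_positive_threshold), np.log10(x[pos].max())
        cut1, cut2 = 10 ** (lo + (hi - lo) / 3), 10 ** (lo + 2 * (hi - lo) / 3)
    else:
        lo, hi = egfp_positive_threshold, x[pos].max()
        cut1, cut2 = lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3
    labels[pos & (x < cut1)] = "Dim"
    labels[pos & (x >= cut1) & (x < cut2)] = "Mid"
    labels[pos & (x >= cut2)] = "Bright"
    empty = tuple(s for s in ("Dim", "Mid", "Bright") if not (labels == s).any())
    return GateResult(
        labels=labels,
        tdtomato_threshold=tdtomato_threshold,
        egfp_threshold=egfp_positive_threshold,
        tertile_cutpoints=(float(cut1), float(cut2)),
        scale=scale,
        empty_tertiles=empty,
    )


def cell_cycle_fractions(
    dna_content: Sequence[float] | np.ndarray,
    min_events: int = 50,
    threshold_factor: float = 1.5,
    n_bins: int = 128,
) -> dict:
    """G0/G1 versus S/G2/M fractions from a DNA-content histogram.

    The 2N mode is located as the lowest prominent histogram peak; events
    above ``threshold_factor`` x mode (default 1.5, the midpoint of the 2N
    and 4N peaks) are counted as S/G2/M.  Returns a dict with keys
    ``g0_g1``, ``s_g2_m``, ``mode_2n`` and ``undefined`` (set when fewer
    than ``min_events`` events are supplied).
    """
    x = np.asarray(dna_content, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_events:
        return {"g0_g1": None, "s_g2_m": None, "mode_2n": None, "undefined": True}
    hist, edges = np.histogram(x, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    peaks, _ = find_peaks(hist, height=0.10 * hist.max())
    mode_2n = centers[peaks[0]] if len(peaks) else centers[np.argmax(hist)]
    threshold = threshold_factor * mode_2n
    s_g2_m = float(np.mean(x > threshold))
    return {
        "g0_g1": 1.0 - s_g2_m,
        "s_g2_m": s_g2_m,
        "mode_2n": float(mode_2n),
        "undefined": False,
    }


def kit_composition(
    germ_events: pd.DataFrame,
    labels: pd.Series,
    kit_threshold: float,
    column: str = "kit",
) -> dict:
    """Overall KIT+ fraction of the germline and the subset makeup of KIT+.

    Returns ``overall_fraction`` (share of germ events above the KIT
    threshold) and ``composition``, the distribution of eGFP subset labels
    among KIT+ events (sums to 1); composition is ``None``-flagged when no
    event is KIT+.
    """
    if column not in germ_events.columns:
        raise ValueError(f"events table has no {column!r} column")
    kit_pos = germ_events[column].to_numpy(dtype=float) > kit_threshold
    overall = float(np.mean(kit_pos)) if len(germ_events) else 0.0
    if not kit_pos.any():
        return {"overall_fraction": overall, "composition": None, "undefined": True}
    comp = (
        labels[kit_pos].value_counts(normalize=True)
        .reindex(SUBSET_ORDER, fill_value=0.0)
    )
    return {"overall_fraction": overall, "composition": comp, "undefined": False}


def kinetics_table(
    counts_by_age: pd.DataFrame,
    cells_per_event: float | dict = 1.0,
    plateau_tol: float = 0.15,
    plateau_run: int = 2,
    s_g2_m_by_age: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Developmental-kinetics summary across ordered ages.

    ``counts_by_age`` is an age x subset table of gated event counts (rows
    in developmental order).  Returns a long-format table with, per age and
    subset: event count, absolute cells per animal (count x conversion
    factor), percent of the germline, fold-change versus the previous age
    (NaN for the first age or a zero previous count, with ``fold_undefined``
    set), optional S/G2/M fraction, and a plateau flag raised at the first
    age opening a run of ``plateau_run`` consecutive intervals whose
    fold-changes stay within ``plateau_tol`` of 1.
    """
    if len(counts_by_age) < 1:
        raise ValueError("need at least one age")
    ages = list(counts_by_age.index)
    rows = []
    for subset in counts_by_age.columns:
        counts = counts_by_age[subset].to_numpy(dtype=float)
        factor = cells_per_event.get(subset, 1.0) if isinstance(cells_per_event, dict) else cells_per_event
        folds = np.full(len(ages), np.nan)
        undefined = np.zeros(len(ages), dtype=bool)
        undefined[0] = True
        for i in range(1, len(ages)):
            if counts[i - 1] > 0:
                folds[i] = counts[i] / counts[i - 1]
            else:
                undefined[i] = True
        near_one = np.isfinite(folds) & (np.abs(folds - 1.0) <= plateau_tol)
        plateau_at = None
        for i in range(1, len(ages) - plateau_run + 2):
            window = near_one[i : i + plateau_run]
            if len(window) == plateau_run and window.all():
                plateau_at = i
                break
        total = counts_by_age.sum(axis=1).to_numpy(dtype=float)
        for i, age in enumerate(ages):
            rows.append(dict(
                age=age,
                subset=subset,
                event_count=counts[i],
                cells_per_animal=counts[i] * factor,
                percent_of_germline=(100.0 * counts[i] / total[i]) if total[i] > 0 else np.nan,
                fold_change=folds[i],
                fold_undefined=bool(undefined[i]),
                plateau=(plateau_at is not None and i == plateau_at),
                s_g2_m=(
                    s_g2_m_by_age.loc[age, subset]
                    if s_g2_m_by_age is not None else np.nan
                ),
            ))
    return pd.DataFrame(rows)
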