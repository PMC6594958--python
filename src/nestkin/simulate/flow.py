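"""Synthetic per-event flow-cytometry tables with known subset structure.

Each simulated sample (one developmental age) contains germ cells carrying a
tdTomato lineage label and a spread of eGFP reporter intensities, plus
tdTomato-negative non-germ cells.  Germ subsets (Bright/Mid/Dim/eGFP-) are
drawn from disjoint log10-eGFP bands aligned to equal thirds of the positive
range, with a configurable margin inside each third so that tertile gating
recovers the subsets exactly.  DNA content follows a standard univariate
model: a 2N peak, a 4N peak at twice its mode, and an S-phase bridge uniform
between the peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SubsetSpec", "FlowSimConfig", "simulate_flow_events"]

GERM_SUBSETS = ("Bright", "Mid", "Dim", "eGFPneg")


@dataclass
class SubsetSpec:
    """Per-subset composition of one simulated sample.

    ``s_g2_m_fraction`` is the share of events in S/G2/M; of those, a
    fraction ``s_phase_share`` transits S (uniform DNA content between the
    2N and 4N peaks) and the remainder sit at the 4N peak.  ``kit_fraction``
    is the share of KIT+ events.
    """

    count: int
    s_g2_m_fraction: float = 0.0
    kit_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("subset count must be >= 0")
        for frac in (self.s_g2_m_fraction, self.kit_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class FlowSimConfig:
    """Design of a multi-age flow-cytometry experiment.

    ``subsets`` maps age -> subset name -> :class:`SubsetSpec`, where subset
    names are Bright/Mid/Dim/eGFPneg for germ cells plus "nongerm".  eGFP
    bands are equal log10 thirds of ``(egfp_log_min, egfp_log_max)`` shrunk
    by ``band_margin`` on each side, ordered Bright > Mid > Dim; eGFP- and
    non-germ events sit below the positive threshold.
    """

    ages: Sequence[str]
    subsets: Mapping[str, Mapping[str, SubsetSpec]]
    egfp_log_min: float = 1.0
    egfp_log_max: float = 4.0
    band_margin: float = 0.1
    tdtomato_germ_log: tuple[float, float] = (3.0, 0.15)  # log10 mean, sd
    tdtomato_background_log: tuple[float, float] = (1.0, 0.2)
    dna_2n_mode: float = 100.0
    dna_cv: float = 0.05
    s_phase_share: float = 0.05
    kit_positive_log: tuple[float, float] = (3.0, 0.15)
    kit_negative_log: tuple[float, float] = (1.0, 0.2)

    def __post_init__(self) -> None:
        if len(self.ages) == 0:
            raise ValueError("age list must be non-empty")
        missing = [a for a in self.ages if a not in self.subsets]
        if missing:
            raise ValueError(f"no subset specs for ages: {missing}")
        if not self.egfp_log_min < self.egfp_log_max:
            raise ValueError("eGFP log range inverted")
        if not 0.0 <= self.band_margin < 0.5:
            raise ValueError("band_margin must lie in [0, 0.5)")
        if not 0.0 <= self.s_phase_share <= 1.0:
            raise ValueError("s_phase_share must lie in [0, 1]")
        for age in self.ages:
            for name in self.subsets[age]:
                if name not in GERM_SUBSETS + ("nongerm",):
                    raise ValueError(f"unknown subset name {name!r}")

    def egfp_band(self, subset: str) -> tuple[float, float]:
        """Log10-eGFP sampling band for a germ subset (Dim < Mid < Bright)."""
        lo, hi = self.egfp_log_min, self.egfp_log_max
        width = (hi - lo) / 3.0
        order = {"Dim": 0, "Mid": 1, "Bright": 2}
        if subset in order:
            b_lo = lo + order[subset] * width
            return (b_lo + self.band_margin * width,
                    b_lo + (1.0 - self.band_margin) * width)
        # eGFP-negative: below the positive threshold with the same margin.
        return (lo - 1.0, lo - self.band_margin * width)


def _sample_dna(rng: np.random.Generator, n: int, config: FlowSimConfig,
                s_g2_m_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """DNA content values and boolean S/G2/M truth flags for n events."""
    mode2n = config.dna_2n_mode
    sd = config.dna_cv * mode2n
    cycling = rng.random(n) < s_g2_m_fraction
    dna = rng.normal(mode2n, sd, n)
    n_cyc = int(cycling.sum())
    if n_cyc:
        in_s = rng.random(n_cyc) < config.s_phase_share
        vals = np.where(
            in_s,
            rng.uniform(mode2n, 2 * mode2n, n_cyc),
            rng.normal(2 * mode2n, 2 * sd, n_cyc),
        )
        dna[cycling] = vals
    return np.abs(dna), cycling


def simulate_flow_events(
    config: FlowSimConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one event table across ages, plus per-event truth labels.

    Returns ``(events, truth)``: ``events`` has columns age, tdTomato, eGFP,
    dna_content, kit; ``truth`` adds subset, is_germ, s_g2_m and kit_positive.
    Event counts per subset match the config exactly; identical config and
    seed reproduce the tables bit for bit.
    """
    rng = np.random.default_rng(seed)
    ev_rows: list[pd.DataFrame] = []
    for age in config.ages:
        for subset in GERM_SUBSETS + ("nongerm",):
            spec = config.subsets[age].get(subset)
            if spec is None or spec.count == 0:
                continue
            n = spec.count
            is_germ = subset != "nongerm"
            if is_germ:
                td = 10 ** rng.normal(*config.tdtomato_germ_log, size=n)
                lo, hi = config.egfp_band(subset)
                egfp = 10 ** rng.uniform(lo, hi, n)
            else:
                td = 10 ** rng.normal(*config.tdtomato_background_log, size=n)
                neg_lo, neg_hi = config.egfp_band("eGFPneg")
                egfp = 10 ** rng.uniform(neg_lo, neg_hi, n)
            dna, cycling = _sample_dna(rng, n, config, spec.s_g2_m_fraction)
            kit_pos = rng.random(n) < spec.kit_fraction
            kit = np.where(
                kit_pos,
                10 ** rng.normal(*config.kit_positive_log, size=n),
                10 ** rng.normal(*config.kit_negative_log, size=n),
            )
            ev_rows.append(pd.DataFrame({
                "age": age,
                "tdTomato": td,
                "eGFP": egfp,
                "dna_content": dna,
                "kit": kit,
                "subset": subset,
                "is_germ": is_germ,
                "s_g2_m": cycling,
                "kit_positive": kit_pos,
            }))
    table = pd.concat(ev_rows, ignore_index=True)
    events = table[["age", "tdTomato", "eGFP", "dna_content", "kit"]].copy()
    truth = table[["age", "subset", "is_germ", "s_g2_m", "kit_positive"]].copy()
    return events, truth


def simulate_unstained_control(
    config: FlowSimConfig, n_events: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Unstained control suspension: background fluorescence only, used to
    set the tdTomato gating threshold."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "tdTomato": 10 ** rng.normal(*config.tdtomato_background_log, size=n_events),
        "eGFP": 10 ** rng.normal(config.egfp_log_min - 1.0, 0.2, size=n_events),
    })
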