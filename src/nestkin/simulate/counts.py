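"""Synthetic gene x cell count matrices with a differentiation continuum.

Each cell carries a latent position ``u`` on a [0, 1] continuum along which
a stem-cell-associated gene program (expected expression decreasing in
``u``) runs opposite a differentiation-associated program (increasing in
``u``), as germline transcriptomes do between the stem-cell and
differentiating poles.  A rare subpopulation (~10% by default, emulating
the stem-cell pool's share of the germline) sits at the low-``u`` end and
additionally expresses a dedicated marker set.  Counts are negative
binomial over log-normal library sizes with optional extra dropout;
mitochondrial genes absorb a per-cell truth fraction of the library, and an
optional share of planted low-quality cells (high mito, shallow library)
plus Dazl/Ddx4-negative somatic cells exercise the QC and germ-selection
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["ContinuumSimConfig", "simulate_counts"]

DEFAULT_SSC_GENES = ("Id4", "Etv5", "Lhx1", "Ret", "Gfra1", "Bcl6b", "Eomes", "Pax7")
DEFAULT_DIFF_GENES = ("Dnmt3a", "Sohlh1", "Kit", "Stra8", "Neurog3", "Sox3", "Dnmt3b", "Rarg")
DEFAULT_HOUSEKEEPING = ("Dazl", "Ddx4", "Actb", "Gapdh", "Rpl13a", "B2m")
DEFAULT_MITO_GENES = ("mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Cytb", "mt-Atp6")


@dataclass
class ContinuumSimConfig:
    """Design of a simulated multi-age droplet scRNA-seq experiment.

    ``program_effect_log2`` is the log2-fold range each program spans across
    the full continuum; the rare population is assigned deterministically
    (``round(fraction * n)`` cells per age) at the low-``u`` end and
    expresses ``rare_marker_genes`` at ``rare_marker_effect_log2`` above
    baseline.  ``u_beta`` gives per-age Beta parameters for the continuum
    position of non-rare cells.
    """

    n_cells: Mapping[str, int] = field(default_factory=lambda: {"P6": 1000})
    n_genes: int = 500
    n_replicates_per_age: int = 2
    ssc_genes: Sequence[str] = DEFAULT_SSC_GENES
    diff_genes: Sequence[str] = DEFAULT_DIFF_GENES
    housekeeping_genes: Sequence[str] = DEFAULT_HOUSEKEEPING
    mito_genes: Sequence[str] = DEFAULT_MITO_GENES
    rare_marker_genes: Sequence[str] = tuple(f"RareMk{i}" for i in range(1, 21))
    rare_fraction: float = 0.10
    program_effect_log2: float = 2.0
    rare_marker_effect_log2: float = 4.0
    u_beta: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    rare_u_beta: tuple[float, float] = (1.0, 9.0)
    nb_dispersion: float = 10.0
    dropout_rate: float = 0.05
    library_size_log: tuple[float, float] = (np.log(5000.0), 0.3)
    mito_beta: tuple[float, float] = (2.0, 30.0)
    low_quality_fraction: float = 0.0
    soma_fraction: float = 0.0

    def __post_init__(self) -> None:
        panels = [set(self.ssc_genes), set(self.diff_genes),
                  set(self.housekeeping_genes), set(self.mito_genes),
                  set(self.rare_marker_genes)]
        total = sum(len(p) for p in panels)
        if len(set().union(*panels)) != total:
            raise ValueError("gene panels must be disjoint")
        if not 0.0 < self.rare_fraction < 0.5:
            raise ValueError("rare_fraction must lie in (0, 0.5)")
        n_named = total
        if self.n_genes < n_named + 1:
            raise ValueError(f"n_genes must exceed the {n_named} named panel genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    def gene_names(self) -> list[str]:
        named = (list(self.ssc_genes) + list(self.diff_genes)
                 + list(self.housekeeping_genes) + list(self.mito_genes)
                 + list(self.rare_marker_genes))
        filler = [f"Gene{i}" for i in range(1, self.n_genes - len(named) + 1)]
        return named + filler


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean mu and dispersion theta (var = mu + mu^2/theta)."""
    mu = np.maximum(mu, 1e-12)
    return rng.negative_binomial(theta, theta / (theta + mu))


def simulate_counts(
    config: ContinuumSimConfig, seed: int = 0
) -> ad.AnnData:
    """Simulate a counts AnnData (cells x genes) with full truth in ``obs``.

    ``obs`` carries: library, age, ``u`` (continuum position), ``rare``,
    ``mito_fraction`` (truth value used in generation), ``low_quality``,
    ``is_germ``.  ``var`` carries a ``panel`` column naming each gene's
    program.  Same config and seed reproduce the matrix exactly.
    """
    rng = np.random.default_rng(seed)
    genes = config.gene_names()
    g_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    obs_rows = []
    rel_rows = []
    mito_idx = [g_index[g] for g in config.mito_genes]
    ssc_idx = [g_index[g] for g in config.ssc_genes]
    diff_idx = [g_index[g] for g in config.diff_genes]
    hk_idx = [g_index[g] for g in config.housekeeping_genes]
    rare_idx = [g_index[g] for g in config.rare_marker_genes]
    filler_idx = [i for i in range(n_genes)
                  if i not in set(mito_idx + ssc_idx + diff_idx + hk_idx + rare_idx)]

    # Baseline relative abundances (linear scale, arbitrary units).
    base = np.zeros(n_genes)
    base[hk_idx] = 30.0
    base[ssc_idx] = 4.0
    base[diff_idx] = 4.0
    base[rare_idx] = 2.0 ** (-2.0)
    base[filler_idx] = 10 ** rng.uniform(-1.0, 0.8, len(filler_idx))

    eff = config.program_effect_log2
    for age, n in config.n_cells.items():
        if n <= 0:
            raise ValueError("n_cells must be positive for every age")
        n_rare = int(round(config.rare_fraction * n))
        n_soma = int(round(config.soma_fraction * n))
        a, b = config.u_beta.get(age, (1.0, 1.0))
        u = rng.beta(a, b, n)
        rare = np.zeros(n, dtype=bool)
        rare[:n_rare] = True
        u[rare] = rng.beta(*config.rare_u_beta, n_rare)
        soma = np.zeros(n, dtype=bool)
        if n_soma:
            soma[-n_soma:] = True
        lowq = rng.random(n) < config.low_quality_fraction
        mito_frac = rng.beta(*config.mito_beta, n)
        mito_frac[lowq] = rng.uniform(0.30, 0.60, int(lowq.sum()))
        replicate = rng.integers(config.n_replicates_per_age, size=n)
        for i in range(n):
            rel = base.copy()
            if soma[i]:
                # Somatic contaminant: no germ program at all.
                rel[ssc_idx] = 0.0
                rel[diff_idx] = 0.0
                rel[[g_index["Dazl"], g_index["Ddx4"]]] = 0.0
            else:
                rel[ssc_idx] = base[ssc_idx] * 2.0 ** (eff * (1.0 - u[i]))
                rel[diff_idx] = base[diff_idx] * 2.0 ** (eff * u[i])
                if rare[i]:
                    rel[rare_idx] = base[rare_idx] * 2.0 ** config.rare_marker_effect_log2
            rel_rows.append(rel)
            obs_rows.append(dict(
                age=age,
                library=f"{age}#{replicate[i] + 1}",
                u=float(u[i]),
                rare=bool(rare[i]),
                mito_fraction=float(mito_frac[i]),
                low_quality=bool(lowq[i]),
                is_germ=not soma[i],
            ))

    rel = np.vstack(rel_rows)
    obs = pd.DataFrame(obs_rows)
    n_cells = len(obs)

    # Mito genes absorb the truth mito fraction; the rest share 1 - m.
    mito_mask = np.zeros(n_genes, dtype=bool)
    mito_mask[mito_idx] = True
    rel[:, mito_mask] = 0.0
    row_sum = rel.sum(axis=1, keepdims=True)
    p = rel / row_sum * (1.0 - obs["mito_fraction"].to_numpy()[:, None])
    p[:, mito_idx] = obs["mito_fraction"].to_numpy()[:, None] / len(mito_idx)

    lib = rng.lognormal(*config.library_size_log, n_cells)
    lib[obs["low_quality"].to_numpy()] *= 0.2
    mu = lib[:, None] * p
    counts = _nb_sample(rng, mu, config.nb_dispersion)
    if config.dropout_rate > 0:
        counts = counts * (rng.random(counts.shape) >= config.dropout_rate)

    obs.index = [f"cell{i}" for i in range(n_cells)]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    panel = np.array(["other"] * n_genes, dtype=object)
    panel[ssc_idx] = "ssc"
    panel[diff_idx] = "diff"
    panel[hk_idx] = "housekeeping"
    panel[mito_idx] = "mito"
    panel[rare_idx] = "rare_marker"
    var["panel"] = panel

    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var
    )
    return adata
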