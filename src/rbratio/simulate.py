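"""Seeded synthetic data with the statistical structure the pipeline assumes.

Two generators are provided:

* :func:`simulate_expression_panel` — a two-class log10-ratio matrix like
  the 30-cell-line training panel: ``n_signature`` planted differential
  genes (half shifted up in the positive class, half down, each by
  ``effect/2`` about zero) plus ``n_null`` genes with no class difference,
  all with i.i.d. Gaussian noise on the log10 scale. CCND1 and CDKN2A are
  always among the planted genes, CCND1 up and CDKN2A down in the
  RB1-positive class, matching the biology the ratio score exploits.
* :func:`simulate_ct_panel` — a qPCR panel like the 12-line validation
  set: each sample draws a true score x from its class's Gaussian
  ``(ratio_means, ratio_sd)``, then emits triplicate Ct wells for CCND1
  and CDKN2A whose mean difference encodes x at efficiency 2. CDKN2A wells
  are anchored at ``ct_base`` so absolute Ct values stay in a realistic
  band.

Identical configs (including the seed) produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CtTable, ExpressionMatrix, PhenotypeLabels

__all__ = ["SimulationConfig", "simulate_expression_panel", "simulate_ct_panel"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Defaults emulate the study geometry: a 16 + 14 two-class expression
    panel with a 20-gene planted signature (class-mean separation
    ``effect`` = 1.0 log10 units, per-gene noise 0.2) over 200 null genes,
    and a 7 + 5 qPCR panel whose class means on x are 1.2 and -0.4 with
    within-class sd 0.15 and 0.1-cycle replicate noise.
    """

    n_pos: int = 16
    n_neg: int = 14
    n_signature: int = 20
    n_null: int = 200
    effect: float = 1.0  # class-mean shift, log10 units
    noise_sd: float = 0.2  # per-gene log10 noise
    ratio_means: tuple[float, float] = (1.2, -0.4)  # x mean: (positive, negative)
    ratio_sd: float = 0.15  # within-class sd of x
    ct_base: float = 26.0  # CDKN2A anchor, cycles
    ct_rep_sd: float = 0.1  # replicate Ct noise, cycles
    n_replicates: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "n_signature", "n_null", "n_replicates"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("noise_sd", "ratio_sd", "ct_rep_sd"):
            if not (getattr(self, name) > 0):
                raise ConfigError(f"{name} must be > 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation parameter(s): {sorted(unknown)}")
        if "ratio_means" in d:
            d = dict(d, ratio_means=tuple(d["ratio_means"]))
        return cls(**d)


def _check_panel_size(config: SimulationConfig) -> None:
    if config.n_pos + config.n_neg < 4 or config.n_pos < 2 or config.n_neg < 2:
        raise ConfigError("panel needs >= 2 samples per class and >= 4 total")


def _sample_ids(config: SimulationConfig) -> tuple[list[str], PhenotypeLabels]:
    ids = [f"POS{i + 1:02d}" for i in range(config.n_pos)] + [
        f"NEG{i + 1:02d}" for i in range(config.n_neg)
    ]
    labels = PhenotypeLabels(
        {s: (1 if s.startswith("POS") else 0) for s in ids}
    )
    return ids, labels


def simulate_expression_panel(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, PhenotypeLabels, tuple[str, ...]]:
    """Generate (matrix, labels, planted gene ids).

    Planted genes alternate direction, starting with CCND1 (up in the
    positive class) and CDKN2A (down); a planted gene's class means are
    +effect/2 and -effect/2. Null genes have mean 0 in both classes.
    Requires ``n_signature >= 2`` so both marker genes exist.
    """
    _check_panel_size(config)
    if config.n_signature < 2:
        raise ConfigError("n_signature must be >= 2 (CCND1 and CDKN2A are always planted)")
    sample_ids, labels = _sample_ids(config)
    rng = np.random.default_rng(config.seed)

    planted = ["CCND1", "CDKN2A"] + [
        f"SIG{i + 1:04d}" for i in range(config.n_signature - 2)
    ]
    nulls = [f"NULL{i + 1:04d}" for i in range(config.n_null)]
    gene_ids = planted + nulls
    # direction per planted gene: even index up in positive class, odd down
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(len(planted))])
    y = labels.vector(sample_ids)  # 1 for positive
    class_sign = np.where(y == 1, 1.0, -1.0)  # shape (n_samples,)
    means = np.zeros((len(gene_ids), len(sample_ids)))
    means[: len(planted)] = (config.effect / 2.0) * signs[:, None] * class_sign[None, :]
    values = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    matrix = ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)
    return matrix, labels, tuple(planted)


def simulate_ct_panel(
    config: SimulationConfig,
) -> tuple[CtTable, PhenotypeLabels, dict[str, float]]:
    """Generate (Ct table, labels, true x per sample).

    Per sample: draw x from the class's ratio distribution, set the CDKN2A
    well mean at ``ct_base`` and the CCND1 well mean at
    ``ct_base - x / log10(2)`` (so mean dCt * log10(2) = x), then add
    independent N(0, ct_rep_sd) noise per well.
    """
    _check_panel_size(config)
    sample_ids, labels = _sample_ids(config)
    rng = np.random.default_rng(config.seed)
    mu_pos, mu_neg = config.ratio_means
    rows: list[tuple[str, str, int, float]] = []
    truth: dict[str, float] = {}
    for sid in sample_ids:
        mu = mu_pos if labels[sid] == 1 else mu_neg
        x = float(rng.normal(mu, config.ratio_sd))
        truth[sid] = x
        ct_cdkn2a = config.ct_base
        ct_ccnd1 = config.ct_base - x / np.log10(2.0)
        for gene, center in (("CCND1", ct_ccnd1), ("CDKN2A", ct_cdkn2a)):
            for rep in range(1, config.n_replicates + 1):
                ct = float(center + rng.normal(0.0, config.ct_rep_sd))
                rows.append((sid, gene, rep, ct))
    table = CtTable(
        pd.DataFrame(rows, columns=["sample_id", "gene", "replicate", "ct"])
    )
    return table, labels, truth
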