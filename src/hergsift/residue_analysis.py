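"""Residue-interaction importance by repeated Kolmogorov-Smirnov testing.

For every interaction-fingerprint column, the IC50 distributions of the
compounds carrying the bit (1) and not carrying it (0) are compared with a
two-sample KS test. The test is repeated over random subsamples of the
compound set (default 100 trials at 80% of the compounds) and the number of
trials reaching p < alpha is the occurrence count: interactions whose count
approaches the trial number split potency robustly, not merely for one lucky
subset. The direction call (lower_ic50 vs higher_ic50) compares group median
IC50 on the full data; the KS statistic itself is invariant under the
monotone log transform, so testing raw or log IC50 is equivalent.

Output rows are sorted by occurrences descending (label ascending on ties)
and formatted as ``NNN_type[occurrences]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import ks_two_sample

logger = logging.getLogger(__name__)

LOWER_IC50 = "lower_ic50"
HIGHER_IC50 = "higher_ic50"


@dataclass(frozen=True)
class ImportanceConfig:
    n_trials: int = 100
    subsample_fraction: float = 0.8
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class ResidueImportanceTable:
    table: pd.DataFrame  # columns: interaction_label, occurrences, direction
    n_trials: int

    def formatted_labels(self) -> list[str]:
        return [
            f"{row.interaction_label}[{row.occurrences}]"
            for row in self.table.itertuples()
        ]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self, tag: str = "") -> str:
        """Single-column text block of bracketed labels (report format)."""
        lines = [tag] if tag else []
        lines.extend(self.formatted_labels())
        return "\n".join(lines) + "\n"


def residue_importance(
    if_table: pd.DataFrame,
    ic50s: pd.Series,
    cfg: ImportanceConfig = ImportanceConfig(),
) -> ResidueImportanceTable:
    """Count, per interaction column, the subsampling trials in which the
    bit=1 vs bit=0 IC50 distributions differ at p < alpha."""
    ic50s = ic50s.reindex(if_table.index)
    if ic50s.isna().any():
        raise ValueError("numeric IC50 required for every fingerprint row")
    # sort rows so the result is invariant to input compound order
    order = np.argsort(if_table.index.to_numpy())
    bits = if_table.to_numpy(int)[order]
    pot = ic50s.to_numpy(float)[order]
    n = len(pot)
    n_sub = max(2, int(round(cfg.subsample_fraction * n)))

    occurrences = np.zeros(if_table.shape[1], dtype=int)
    for trial in range(cfg.n_trials):
        rng = np.random.default_rng([cfg.seed, trial])
        idx = rng.choice(n, n_sub, replace=False)
        sub_bits = bits[idx]
        sub_pot = pot[idx]
        for col in range(bits.shape[1]):
            on = sub_bits[:, col] == 1
            if not on.any() or on.all():
                logger.debug("trial %d: column %s constant in subsample, skipped",
                             trial, if_table.columns[col])
                continue
            _, p = ks_two_sample(sub_pot[on], sub_pot[~on])
            if p < cfg.alpha:
                occurrences[col] += 1

    directions = []
    for col, label in enumerate(if_table.columns):
        on = bits[:, col] == 1
        if not on.any() or on.all():
            logger.warning("column %s constant across all data", label)
            directions.append(LOWER_IC50)
            continue
        directions.append(
            LOWER_IC50 if np.median(pot[on]) < np.median(pot[~on]) else HIGHER_IC50
        )

    table = pd.DataFrame(
        {
            "interaction_label": list(if_table.columns),
            "occurrences": occurrences,
            "direction": directions,
        }
    ).sort_values(
        ["occurrences", "interaction_label"], ascending=[False, True]
    ).reset_index(drop=True)
    return ResidueImportanceTable(table, cfg.n_trials)
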