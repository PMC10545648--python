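"""Multiverse robustness analysis.

The full pipeline is re-run under a 2x2x2x2 grid of defensible analysis
settings — block length (16 or 20), chance criterion for block validity
(liberal or conservative), inclusion of EEG-bad trials, and inclusion of
grating orientation as an extra predictor — yielding 16 cells.  Each cell
reports the detection-threshold awareness effect, the identification-
threshold effect, and their difference for VAN and LP with 95% CIs.  The
cell (16, liberal, exclude-bad, no-orientation) is the main analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .inference import GibbsConfig, ModelSpec, fit_model
from .selection import SelectionConfig, apply_exclusions, center_opacity, \
    partition_and_flag

__all__ = ["MultiverseCell", "run_cell", "run_multiverse", "summarize_robustness",
           "MAIN_CELL"]

EFFECTS = ("detection_effect", "identification_effect", "threshold:awareness")
MAIN_CELL = dict(block_length=16, criterion="liberal",
                 include_bad_eeg=False, include_orientation=False)


@dataclass(frozen=True)
class MultiverseCell:
    block_length: int
    criterion: str                 # liberal | conservative
    include_bad_eeg: bool
    include_orientation: bool

    @property
    def cell_id(self) -> str:
        return (f"b{self.block_length}_{self.criterion}"
                f"_{'incl' if self.include_bad_eeg else 'excl'}bad"
                f"_{'orient' if self.include_orientation else 'noorient'}")

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig.preset(self.block_length, self.criterion,
                                      include_bad_eeg=self.include_bad_eeg)


def grid() -> list[MultiverseCell]:
    return [MultiverseCell(bl, cr, bad, orient)
            for bl, cr, bad, orient in product(
                (16, 20), ("liberal", "conservative"), (False, True),
                (False, True))]


def run_cell(trials: pd.DataFrame, cell: MultiverseCell,
             sampler: GibbsConfig, seed: int | np.random.SeedSequence,
             outcomes: tuple[str, ...] = ("van_amp", "lp_amp")) -> list[dict]:
    """Run selection + full-interaction model for one cell; returns tidy rows."""
    selected = partition_and_flag(trials, cell.selection_config())
    selected = center_opacity(selected)
    analysis, report = apply_exclusions(selected, cell.selection_config())
    rows = []
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    outcome_seeds = dict(zip(outcomes, ss.spawn(len(outcomes))))
    for outcome in outcomes:
        base = dict(cell_id=cell.cell_id, block_length=cell.block_length,
                    criterion=cell.criterion,
                    include_bad_eeg=cell.include_bad_eeg,
                    include_orientation=cell.include_orientation,
                    outcome=outcome, n_trials=report.get("n_retained", 0))
        if analysis.empty:
            rows.append({**base, "failed": True})
            continue
        try:
            spec = ModelSpec(formula_id="full_interaction", outcome=outcome,
                             include_orientation=cell.include_orientation)
            fit = fit_model(analysis, spec, sampler, outcome_seeds[outcome])
            fit.summarize(extra=("detection_effect", "identification_effect"))
        except ValueError:
            rows.append({**base, "failed": True})
            continue
        for eff in EFFECTS:
            s = fit.summaries[eff]
            rows.append({**base, "failed": False, "effect": eff,
                         "mean": s.mean, "ci_low": s.ci_low,
                         "ci_high": s.ci_high, "pd": s.pd, "bf10": s.bf10,
                         "converged": fit.converged, "max_rhat": fit.max_rhat})
    return rows


def run_multiverse(trials: pd.DataFrame, sampler: GibbsConfig | None = None,
                   seed: int = 0,
                   outcomes: tuple[str, ...] = ("van_amp", "lp_amp")
                   ) -> pd.DataFrame:
    """Execute all 16 cells; per-cell seeds derive deterministically from
    ``seed``, so cell results do not depend on execution order.  A cell
    whose analysis set is empty is marked failed and the run continues.
    """
    sampler = GibbsConfig.fast() if sampler is None else sampler
    cells = grid()
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(len(cells))
    rows = []
    for cell, cseed in zip(cells, cell_seeds):
        rows.extend(run_cell(trials, cell, sampler, cseed, outcomes))
    return pd.DataFrame(rows)


def summarize_robustness(cells: pd.DataFrame) -> pd.DataFrame:
    """Sign consistency and CI behavior across cells, per outcome x effect.

    For each effect: the count of successful cells, how many share the sign
    of the cross-cell median estimate, how many have 95% CIs excluding 0,
    and the min/max estimate.
    """
    ok = cells[~cells.get("failed", False).astype(bool)]
    if ok.empty:
        raise ValueError("no successful multiverse cells to summarize")
    out = []
    for (outcome, eff), g in ok.groupby(["outcome", "effect"]):
        sign = np.sign(np.median(g["mean"]))
        out.append(dict(
            outcome=outcome, effect=eff, n_cells=len(g),
            n_sign_consistent=int((np.sign(g["mean"]) == sign).sum()),
            n_ci_excluding_zero=int(((g["ci_low"] > 0) | (g["ci_high"] < 0)).sum()),
            min_estimate=float(g["mean"].min()),
            max_estimate=float(g["mean"].max()),
        ))
    return pd.DataFrame(out)
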