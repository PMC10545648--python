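"""At-threshold trial selection.

Staircase data only approximate the awareness threshold, so the analysis
retains stretches of trials in which aware and unaware reports are balanced
the way chance responding at threshold would produce them.  Consecutive
trials of each staircase are partitioned into fixed-length blocks; a block
is *valid* when its aware count lies in the symmetric range around n/2 whose
Binomial(n, 0.5) probability stays below a chance criterion.  Within valid
blocks opacity is mean-centered to remove slow drift.  Subjects keep a
threshold condition only with at least ``min_trials_per_cell`` trials in
both the aware and the unaware cell, and single trials are dropped when an
amplitude deviates more than ``amplitude_sd_cut`` SDs from the grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = ["SelectionConfig", "BlockRange", "valid_block_range",
           "partition_and_flag", "center_opacity", "apply_exclusions",
           "CRITERION_PRESETS"]

#: Chance-criterion presets by block length: cumulative-probability bounds
#: for the liberal and conservative variants of the block-validity rule.
CRITERION_PRESETS: dict[int, dict[str, float]] = {
    16: {"liberal": 0.80, "conservative": 0.55},
    20: {"liberal": 0.75, "conservative": 0.50},
}


@dataclass(frozen=True)
class SelectionConfig:
    """Settings of the at-threshold selection stage."""

    block_length: int = 16
    chance_criterion: float = 0.80
    min_trials_per_cell: int = 25
    amplitude_sd_cut: float = 3.0
    include_bad_eeg: bool = False

    def __post_init__(self) -> None:
        if self.block_length < 2 or self.block_length % 2:
            raise ValueError("block_length must be even and >= 2")
        if not 0.0 < self.chance_criterion < 1.0:
            raise ValueError("chance_criterion must lie in (0, 1)")

    @classmethod
    def preset(cls, block_length: int, criterion: str, **kw) -> "SelectionConfig":
        return cls(block_length=block_length,
                   chance_criterion=CRITERION_PRESETS[block_length][criterion], **kw)


class BlockRange(NamedTuple):
    lo: int
    hi: int
    degenerate: bool


def valid_block_range(n: int, criterion: float) -> BlockRange:
    """Aware-count range expected by chance in a block of ``n`` trials.

    Returns the widest symmetric range ``[n/2 - k, n/2 + k]`` whose
    Binomial(n, 0.5) probability is strictly below ``criterion``.  When even
    the single central count has probability >= criterion no range
    qualifies, and the result carries ``degenerate=True`` with the central
    count as a fallback.
    """
    if n < 2 or n % 2:
        raise ValueError("block length must be even and >= 2")
    if not 0.0 < criterion < 1.0:
        raise ValueError("criterion must lie in (0, 1)")
    c = n // 2
    best = None
    for k in range(c + 1):
        p = binom.cdf(c + k, n, 0.5) - binom.cdf(c - k - 1, n, 0.5)
        if p < criterion:
            best = k
        else:
            break
    if best is None:
        return BlockRange(c, c, True)
    return BlockRange(c - best, c + best, False)


def partition_and_flag(trials: pd.DataFrame, cfg: SelectionConfig) -> pd.DataFrame:
    """Assign block indices per staircase and flag valid blocks.

    Consecutive non-catch trials of each staircase (in ``trial_index``
    order, per subject) form blocks of ``cfg.block_length``; a trailing
    partial block is flagged invalid.  ``block_valid`` is true when the
    block's aware count lies within :func:`valid_block_range`.  Catch trials
    get ``block_index = -1`` and ``block_valid = False``.
    """
    rng_ = valid_block_range(cfg.block_length, cfg.chance_criterion)
    out = trials.copy()
    out["block_index"] = -1
    out["block_valid"] = False
    L = cfg.block_length
    for (_, sc), idx in out.groupby(["subject_id", "staircase"]).groups.items():
        if sc == "catch":
            continue
        idx = out.loc[idx].sort_values("trial_index").index
        pos = np.arange(len(idx))
        blocks = pos // L
        out.loc[idx, "block_index"] = blocks
        aware = out.loc[idx, "aware"].to_numpy()
        for b in np.unique(blocks):
            members = idx[blocks == b]
            if len(members) < L or rng_.degenerate:
                continue
            count = int(np.nansum(aware[blocks == b]))
            out.loc[members, "block_valid"] = rng_.lo <= count <= rng_.hi
    return out


def center_opacity(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean-center opacity within each block (per subject and staircase).

    Removes slow drift of the staircase so only relative opacity differences
    within a block enter the models.  Centered values sum to zero per block.
    """
    if "block_index" not in trials.columns:
        raise ValueError("run partition_and_flag before center_opacity")
    out = trials.copy()
    grp = out.groupby(["subject_id", "staircase", "block_index"])["opacity"]
    out["opacity_centered"] = out["opacity"] - grp.transform("mean")
    out.loc[out["staircase"] == "catch", "opacity_centered"] = 0.0
    return out


def apply_exclusions(trials: pd.DataFrame, cfg: SelectionConfig
                     ) -> tuple[pd.DataFrame, dict]:
    """Build the analysis set and an exclusion report.

    Stages, in order: (1) keep only valid-block non-catch trials and, unless
    ``cfg.include_bad_eeg``, drop trials flagged bad during EEG
    preprocessing; (2) per subject x threshold, drop the threshold condition
    when either awareness cell has fewer than ``min_trials_per_cell`` trials
    (a subject failing both thresholds is dropped entirely); (3) single-pass
    amplitude outlier removal, separately for the VAN and LP measures,
    cutting trials more than ``amplitude_sd_cut`` SDs from the grand mean
    over all retained trials and subjects.  The returned report reconciles
    counts at every stage.
    """
    report: dict = {"n_input": int(len(trials))}
    work = trials[(trials["staircase"] != "catch") & trials["block_valid"]].copy()
    report["n_valid_blocks"] = int(len(work))
    if not cfg.include_bad_eeg and "eeg_bad" in work.columns:
        n0 = len(work)
        work = work[~work["eeg_bad"].astype(bool)]
        report["n_bad_eeg_dropped"] = int(n0 - len(work))
    else:
        report["n_bad_eeg_dropped"] = 0

    keep_idx = []
    cell_drops = 0
    for (subj, sc), g in work.groupby(["subject_id", "staircase"]):
        counts = g["aware"].value_counts()
        if min(counts.get(0, 0), counts.get(1, 0)) >= cfg.min_trials_per_cell:
            keep_idx.append(g.index)
        else:
            cell_drops += len(g)
    work = work.loc[np.concatenate(keep_idx)] if keep_idx else work.iloc[0:0]
    report["n_min_cell_dropped"] = int(cell_drops)

    # outliers are flagged separately per measure: a trial extreme on VAN is
    # dropped only from the VAN analysis, and vice versa
    work = work.copy()
    for col in ("van_amp", "lp_amp"):
        flag = f"{col}_outlier"
        work[flag] = False
        if col in work.columns and len(work):
            v = work[col].to_numpy(dtype=float)
            m, s = np.nanmean(v), np.nanstd(v)
            if s > 0:
                work[flag] = np.abs(v - m) > cfg.amplitude_sd_cut * s
        report[f"n_outliers_{col}"] = int(work[flag].sum())
    report["n_retained"] = int(len(work))
    if work.empty:
        report["empty"] = True
    return work, report
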