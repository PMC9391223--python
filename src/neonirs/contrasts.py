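"""Centred sum/Helmert contrast coding for the trial-level mixed models.

Stimulus type is a centred two-level contrast (backward -1/2, forward +1/2).
Participant group and test phase are three-level Helmert contrasts:

* grp1: passive control (-2/3) vs the mean of active control and
  experimental (+1/3 each) — the general effect of training;
* grp2: active control (-1/2) vs experimental (+1/2), passive 0 — the
  specific effect of training content;
* ph1: T0 (-2/3) vs the mean of T1 and T2 (+1/3 each) — the general effect
  of time relative to training;
* ph2: T1 (-1/2) vs T2 (+1/2), T0 coded 0 — the effect of sleep and
  consolidation.

All columns are centred on their observed means before interaction products
are formed, so every predictor (including products) has mean ~0 in the
analysed data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "RAW_CODES", "FIXED_TERMS", "FIXED_TERMS_REDUCED",
    "SUBJECT_RE_TERMS", "SUBJECT_RE_TERMS_REDUCED",
    "code_contrasts", "term_columns",
]

RAW_CODES = {
    "stim": {"backward": -0.5, "forward": 0.5},
    "grp1": {"passive": -2 / 3, "active": 1 / 3, "experimental": 1 / 3},
    "grp2": {"passive": 0.0, "active": -0.5, "experimental": 0.5},
    "ph1": {"T0": -2 / 3, "T1": 1 / 3, "T2": 1 / 3},
    "ph2": {"T0": 0.0, "T1": -0.5, "T2": 0.5},
}

_FACTOR_OF = {"stim": "stimulus", "grp1": "group", "grp2": "group",
              "ph1": "phase", "ph2": "phase"}

_BASE = ["stim", "grp1", "grp2", "ph1", "ph2"]
# full factorial excluding within-factor products: 5 mains, 8 two-way,
# 4 three-way (17 slopes + intercept)
_TWOWAY = [f"{a}:{b}" for a in ("stim",) for b in ("grp1", "grp2", "ph1", "ph2")] \
        + [f"{g}:{p}" for g in ("grp1", "grp2") for p in ("ph1", "ph2")]
_THREEWAY = [f"stim:{g}:{p}" for g in ("grp1", "grp2") for p in ("ph1", "ph2")]
FIXED_TERMS = ["1"] + _BASE + _TWOWAY + _THREEWAY

# reduced (connectivity) model: no stimulus factor
FIXED_TERMS_REDUCED = ["1", "grp1", "grp2", "ph1", "ph2",
                       "grp1:ph1", "grp1:ph2", "grp2:ph1", "grp2:ph2"]

# by-participant random terms exclude between-participant (group) contrasts
SUBJECT_RE_TERMS = ["1", "stim", "ph1", "ph2", "stim:ph1", "stim:ph2"]
SUBJECT_RE_TERMS_REDUCED = ["1", "ph1", "ph2"]


def code_contrasts(table: pd.DataFrame, stimulus: bool = True,
                   center: bool = True) -> pd.DataFrame:
    """Append centred contrast columns and their interaction products.

    ``table`` must carry ``group`` and ``phase`` columns (and
    ``stimulus_type`` unless ``stimulus=False``).  Returns a new DataFrame of
    design columns named per ``FIXED_TERMS`` (intercept column "1" included).
    """
    n = len(table)
    cols: dict[str, np.ndarray] = {"1": np.ones(n)}
    factors = dict(_FACTOR_OF)
    if not stimulus:
        factors.pop("stim")
    for name, factor in factors.items():
        src = "stimulus_type" if factor == "stimulus" else factor
        codes = RAW_CODES[name]
        vals = table[src].map(codes)
        if vals.isna().any():
            bad = sorted(set(table[src][vals.isna()]))
            raise ValueError(f"unknown {factor} level(s) {bad}")
        x = vals.to_numpy(dtype=float)
        if center:
            x = x - x.mean()
        cols[name] = x
    terms = FIXED_TERMS if stimulus else FIXED_TERMS_REDUCED
    for term in terms:
        if term in cols:
            continue
        parts = term.split(":")
        x = np.ones(n)
        for p in parts:
            x = x * cols[p]
        cols[term] = x
    return pd.DataFrame(cols, index=table.index)


def term_columns(design: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Stack the named design columns into an (n, k) array."""
    return np.column_stack([design[t].to_numpy() for t in terms])
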