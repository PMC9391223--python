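"""Trial-level mixed-effects inference.

`TrialLMM` models single-trial mean amplitudes or peak latencies as a
function of three centred contrast-coded factors (stimulus type, participant
group, test phase) and all their between-factor interactions (17 slopes +
intercept), with maximal uncorrelated random-effects structures by
participant (within-subject terms only) and by channel (all terms).
`fit()` returns a `TrialResults` object carrying REML estimates, s.e.m.,
Satterthwaite df, t and two-tailed p per term, per-channel BLUPs, and
per-channel refits (participant random effects only) feeding
Benjamini-Hochberg FDR channel selection.

The headline terms are the stimulus x group-contrast-2 x phase-contrast-2
interaction for amplitude (training content x consolidation) and
stimulus x group-contrast-2 x phase-contrast-1 for latency (training
content x time-since-training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .contrasts import (FIXED_TERMS, SUBJECT_RE_TERMS, code_contrasts,
                        term_columns)
from .mixedlm import VarCompMixedLM, VarCompResults, blocks_from_table
from .montage import Montage

AMPLITUDE_TERM = "stim:grp2:ph2"
LATENCY_TERM = "stim:grp2:ph1"

__all__ = ["TrialLMM", "TrialResults", "AnalysisReport", "bh_fdr",
           "per_channel_fit", "run_amplitude_analysis",
           "run_latency_analysis", "AMPLITUDE_TERM", "LATENCY_TERM"]


def _validate_table(table: pd.DataFrame, response: str) -> pd.DataFrame:
    need = {"subject_id", "group", "phase", "channel_id", "stimulus_type",
            response}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    tab = table.dropna(subset=[response]).copy()
    if tab["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    return tab


class TrialLMM:
    """Mixed model for one response column of a trial feature table.

    Parameters
    ----------
    table : long-format TrialFeatureTable (one row per trial x channel).
    response : "mean_amplitude" or "peak_latency" (any numeric column).
    by_channel : include the by-channel random-effects structure
        (switched off for single-channel refits).
    """

    def __init__(self, table: pd.DataFrame, response: str = "mean_amplitude",
                 by_channel: bool = True):
        self.table = _validate_table(table, response)
        self.response = response
        self.by_channel = by_channel and self.table["channel_id"].nunique() > 1
        self.design = code_contrasts(self.table)
        self.X = term_columns(self.design, FIXED_TERMS)
        blocks = blocks_from_table(self.table, self.design, "subject_id",
                                   SUBJECT_RE_TERMS, "participant")
        if self.by_channel:
            blocks += blocks_from_table(self.table, self.design, "channel_id",
                                        FIXED_TERMS, "channel")
        self._core = VarCompMixedLM(self.table[response].to_numpy(), self.X,
                                    blocks, FIXED_TERMS)

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame,
                           response: str = "mean_amplitude") -> "TrialLMM":
        return cls(table, response)

    def fit(self, **kw) -> "TrialResults":
        return TrialResults(self, self._core.fit(**kw))


class TrialResults:
    """Results wrapper: delegates estimates/uncertainties to the REML core
    and adds channel-level views."""

    def __init__(self, model: TrialLMM, core: VarCompResults):
        self.model = model
        self.core = core
        self.fe_params = core.fe_params
        self.bse = core.bse
        self.vcomp = core.vcomp
        self.scale = core.scale
        self.converged = core.converged
        self.singular = core.singular

    def test_term(self, term: str) -> dict:
        return self.core.test_term(term)

    def summary(self, terms: list[str] | None = None) -> pd.DataFrame:
        return self.core.summary(terms)

    def blups(self, term: str) -> pd.Series:
        """Per-channel effect estimates for ``term``: fixed beta + the
        channel's conditional mode.  With zero channel-slope variance all
        channels collapse onto the fixed estimate (complete shrinkage)."""
        if not self.model.by_channel:
            raise ValueError("model was fitted without by-channel terms")
        modes = self.core.blups(f"channel:{term}")
        return modes + float(self.fe_params[term])

    def conditional_modes(self, term: str) -> pd.Series:
        return self.core.blups(f"channel:{term}")


def per_channel_fit(table: pd.DataFrame, channel_id: int,
                    response: str = "mean_amplitude",
                    term: str = AMPLITUDE_TERM,
                    montage: Montage | None = None) -> dict:
    """Refit the same fixed structure to one channel's rows (participant
    random effects only) and emit a channel-table row
    {channel, region, beta, sem, df, t, p}."""
    sub = table[table["channel_id"] == channel_id]
    if sub.empty:
        raise ValueError(f"channel {channel_id} absent from the table")
    res = TrialLMM(sub, response, by_channel=False).fit()
    row = res.test_term(term)
    region = montage.region(channel_id) if montage is not None else ""
    return {"channel": int(channel_id), "region": region,
            "beta": row["beta"], "sem": row["sem"], "df": row["df"],
            "t": row["t"], "p": row["p"]}


@dataclass
class FdrResult:
    pvals: np.ndarray
    qvals: np.ndarray
    selected: np.ndarray       # boolean
    q_star: float
    labels: list = field(default_factory=list)

    @property
    def selected_labels(self) -> list:
        return [l for l, s in zip(self.labels, self.selected) if s]


def bh_fdr(pvals, q_star: float = 0.15, labels=None) -> FdrResult:
    """Benjamini-Hochberg step-up selection at FDR level ``q_star``."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return FdrResult(p, p.copy(), np.zeros(0, bool), q_star, labels or [])
    rej, q, _, _ = multipletests(p, alpha=q_star, method="fdr_bh")
    return FdrResult(p, q, rej, q_star,
                     list(labels) if labels is not None else list(range(p.size)))


@dataclass
class AnalysisReport:
    """Everything one response's analysis produces."""

    response: str
    term: str
    results: TrialResults
    blup_table: pd.DataFrame          # channel, region, blup
    channel_table: pd.DataFrame       # channel, region, beta, sem, df, t, p
    fdr: FdrResult

    @property
    def seed_channels(self) -> list[int]:
        return [int(c) for c in self.fdr.selected_labels]

    def headline(self) -> dict:
        return self.results.test_term(self.term)

    def plot_blups(self, ax=None):
        """Bar chart of the per-channel BLUP map, FDR-selected channels
        highlighted."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        sel = set(self.seed_channels)
        colors = ["C3" if c in sel else "C0"
                  for c in self.blup_table["channel"]]
        ax.bar(self.blup_table["channel"], self.blup_table["blup"],
               color=colors)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("channel")
        ax.set_ylabel(f"BLUP of {self.term}")
        ax.set_title(f"{self.response}: per-channel effect map")
        return ax


def _run_analysis(table: pd.DataFrame, response: str, term: str,
                  montage: Montage | None, q_star: float) -> AnalysisReport:
    res = TrialLMM(table, response).fit()
    channels = sorted(table["channel_id"].unique())
    blup = res.blups(term)
    blup_table = pd.DataFrame({
        "channel": [int(c) for c in blup.index],
        "region": [montage.region(int(c)) if montage else "" for c in blup.index],
        "blup": blup.to_numpy(),
    })
    rows = [per_channel_fit(table, c, response, term, montage)
            for c in channels]
    channel_table = pd.DataFrame(rows)
    fdr = bh_fdr(channel_table["p"].to_numpy(), q_star,
                 labels=channel_table["channel"].tolist())
    return AnalysisReport(response, term, res, blup_table, channel_table, fdr)


def run_amplitude_analysis(table: pd.DataFrame,
                           montage: Montage | None = None,
                           q_star: float = 0.15) -> AnalysisReport:
    """Full amplitude analysis: maximal-model fit, per-channel BLUP map and
    refits of the stimulus x group2 x phase2 (consolidation) interaction,
    and FDR channel selection."""
    return _run_analysis(table, "mean_amplitude", AMPLITUDE_TERM, montage,
                         q_star)


def run_latency_analysis(table: pd.DataFrame,
                         montage: Montage | None = None,
                         q_star: float = 0.15) -> AnalysisReport:
    """Full latency analysis of the stimulus x group2 x phase1
    (time-since-training) interaction."""
    return _run_analysis(table, "peak_latency", LATENCY_TERM, montage, q_star)
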