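"""Resting-state functional connectivity.

For every subject x phase, the 3-min (1,800-sample) oxyhaemoglobin window
preceding the test session yields a channel x channel Pearson correlation
matrix; coefficients are variance-stabilised with Fisher's z = artanh(r).
Pairs involving the FDR-selected seed channels (s seeds among n channels
give s(n-1) - s(s-1)/2 pairs) enter a reduced mixed model — group and phase
contrasts and their products, no stimulus factor — with random effects by
participant (intercept + phase terms) and by channel pair (all terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrasts import (FIXED_TERMS_REDUCED, SUBJECT_RE_TERMS_REDUCED,
                        code_contrasts, term_columns)
from .mixedlm import VarCompMixedLM, VarCompResults, blocks_from_table
from .signals import HemoSeries

CONNECTIVITY_TERM = "grp1:ph2"

__all__ = [
    "SeedSet", "resting_window", "corr_matrix", "fisher_z",
    "enumerate_seed_pairs", "build_pair_table", "ConnectivityLMM",
    "ConnectivityResults", "per_pair_tests", "threshold_network",
    "CONNECTIVITY_TERM",
]


@dataclass(frozen=True)
class SeedSet:
    seed_channels: tuple[int, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.seed_channels:
            raise ValueError("seed set must be nonempty")


def resting_window(series: HemoSeries, test_onset: float,
                   duration: float = 180.0) -> np.ndarray:
    """Extract the window of exactly duration x sampling_rate samples ending
    at the sample just before ``test_onset``.  Returns (channels, samples)
    oxyhaemoglobin."""
    fs = series.sampling_rate
    n = int(round(duration * fs))
    end = int(round(test_onset * fs))
    start = end - n
    if start < 0 or end > series.n_samples:
        raise ValueError("recording does not cover the requested resting "
                         "window")
    return series.hbo[:, start:end]


def corr_matrix(window: np.ndarray, mask: np.ndarray | None = None,
                ) -> np.ndarray:
    """Pairwise-complete Pearson correlation across channels.

    Masked samples are dropped pairwise; constant channels yield NaN
    (recorded as missing downstream rather than failing the subject).
    """
    w = np.asarray(window, dtype=float)
    if w.shape[1] < 3:
        raise ValueError("need at least 3 samples per channel")
    if mask is None or mask.all():
        sd = w.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(w)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
        np.fill_diagonal(r, 1.0)
        return r
    df = pd.DataFrame(np.where(mask, w, np.nan).T)
    return df.corr(min_periods=3).to_numpy()


def fisher_z(r):
    """Fisher z-transform, z = artanh(r); monotone and odd."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) >= 1):
        # diagonal ones are excluded by callers; reject genuine |r|>=1 input
        raise ValueError("|r| must be < 1 for the Fisher transform")
    return np.arctanh(r)


def enumerate_seed_pairs(seeds: SeedSet, n_channels: int,
                         channel_ids: list[int] | None = None,
                         ) -> list[tuple[int, int]]:
    """Unordered channel pairs with at least one seed member, each counted
    once; with s seeds among n channels the count is s(n-1) - s(s-1)/2."""
    ids = channel_ids or list(range(1, n_channels + 1))
    sset = set(seeds.seed_channels)
    if not sset <= set(ids):
        raise ValueError("seed channels must belong to the montage")
    pairs = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if a in sset or b in sset:
                pairs.append((a, b))
    return pairs


def build_pair_table(windows: list[tuple[dict, np.ndarray]],
                     pairs: list[tuple[int, int]],
                     channel_ids: list[int] | None = None) -> pd.DataFrame:
    """Long pair table (subject, group, phase, chan_a, chan_b, r, z) from
    per-recording resting windows.  Undefined correlations (constant
    channels) are excluded with a count in ``DataFrame.attrs``."""
    rows, n_undef = [], 0
    for meta, win in windows:
        ids = channel_ids or list(range(1, win.shape[0] + 1))
        idx = {c: i for i, c in enumerate(ids)}
        r = corr_matrix(win)
        for a, b in pairs:
            rv = r[idx[a], idx[b]]
            if not np.isfinite(rv):
                n_undef += 1
                continue
            rows.append((meta["subject_id"], meta["group"], meta["phase"],
                         a, b, rv, float(np.arctanh(rv))))
    tab = pd.DataFrame(rows, columns=["subject_id", "group", "phase",
                                      "chan_a", "chan_b", "r", "z"])
    tab.attrs["n_undefined"] = n_undef
    return tab


class ConnectivityLMM:
    """Reduced group x phase mixed model on Fisher-z pair values."""

    TERMS = FIXED_TERMS_REDUCED

    def __init__(self, pair_table: pd.DataFrame, by_pair: bool = True):
        need = {"subject_id", "group", "phase", "chan_a", "chan_b", "z"}
        if not need <= set(pair_table.columns):
            raise ValueError(f"pair table lacks {sorted(need - set(pair_table.columns))}")
        if pair_table.empty:
            raise ValueError("empty pair table")
        if not np.all(np.isfinite(pair_table["z"])):
            raise ValueError("z values must be finite")
        tab = pair_table.copy()
        tab["pair"] = tab["chan_a"].astype(str) + "-" + tab["chan_b"].astype(str)
        self.table = tab
        self.design = code_contrasts(tab, stimulus=False)
        self.X = term_columns(self.design, self.TERMS)
        blocks = blocks_from_table(tab, self.design, "subject_id",
                                   SUBJECT_RE_TERMS_REDUCED, "participant")
        if by_pair and tab["pair"].nunique() > 1:
            blocks += blocks_from_table(tab, self.design, "pair",
                                        self.TERMS, "pair")
        self._core = VarCompMixedLM(tab["z"].to_numpy(), self.X, blocks,
                                    self.TERMS)

    def fit(self, **kw) -> "ConnectivityResults":
        return ConnectivityResults(self, self._core.fit(**kw))


class ConnectivityResults:
    def __init__(self, model: ConnectivityLMM, core: VarCompResults):
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

    def summary(self) -> pd.DataFrame:
        """Nine-row fixed-effects table: intercept, 4 main contrasts, 4
        group x phase interactions, in model order."""
        return self.core.summary(self.model.TERMS)

    def blups(self, term: str) -> pd.Series:
        return self.core.blups(f"pair:{term}") + float(self.fe_params[term])


def per_pair_tests(pair_table: pd.DataFrame, term: str = CONNECTIVITY_TERM,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Reduced per-pair refits (participant random effects only): one row
    per pair with beta, sem, df, t, p plus significance at ``alpha``.

    ``DataFrame.attrs`` carries the significant count and its sign split.
    """
    if pair_table.empty:
        raise ValueError("empty pair table")
    rows = []
    for (a, b), sub in pair_table.groupby(["chan_a", "chan_b"], sort=True):
        res = ConnectivityLMM(sub, by_pair=False).fit()
        r = res.test_term(term)
        rows.append({"chan_a": int(a), "chan_b": int(b), "beta": r["beta"],
                     "sem": r["sem"], "df": r["df"], "t": r["t"],
                     "p": r["p"]})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    out.attrs["n_significant"] = int(out["significant"].sum())
    out.attrs["n_positive"] = int((out["significant"] & (out["beta"] > 0)).sum())
    out.attrs["n_negative"] = int((out["significant"] & (out["beta"] < 0)).sum())
    return out


def edge_summary(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Mean z per pair x group x phase."""
    return (pair_table
            .groupby(["chan_a", "chan_b", "group", "phase"], sort=True)["z"]
            .mean().rename("mean_z").reset_index())


def threshold_network(edges: pd.DataFrame, rule: str = "experimental_T0",
                      threshold: float | None = None) -> pd.DataFrame:
    """Display-threshold rule: keep edges with mean z above the absolute
    value of the most negative mean z observed in the experimental group at
    rest (baseline phase by default; ``rule="experimental_all"`` pools all
    phases; an explicit ``threshold`` overrides the rule).

    The applied rule and threshold are recorded in ``DataFrame.attrs``.
    """
    if threshold is None:
        if rule == "experimental_T0":
            sel = (edges["group"] == "experimental") & (edges["phase"] == "T0")
        elif rule == "experimental_all":
            sel = edges["group"] == "experimental"
        else:
            raise ValueError(f"unknown threshold rule {rule!r}")
        if not sel.any():
            raise ValueError("edge summary has no rows for the rule")
        mn = float(edges.loc[sel, "mean_z"].min())
        threshold = abs(mn) if mn < 0 else 0.0
    out = edges[edges["mean_z"] > threshold].copy()
    out.attrs["rule"] = rule
    out.attrs["threshold"] = float(threshold)
    return out
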