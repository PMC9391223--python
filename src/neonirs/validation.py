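"""Simulation-based validation of the inference layer.

Reduced-scale study simulations (fewer subjects, channels and trials than
the full design, chosen so a validation batch runs in minutes on one CPU)
that measure estimator bias, confidence-interval coverage, type-I error and
false-discovery control for the trial-level and connectivity mixed models.
Used by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .connectivity import CONNECTIVITY_TERM, ConnectivityLMM
from .lmm import AMPLITUDE_TERM, TrialLMM, bh_fdr
from .simulate import simulate_feature_table, simulate_pair_table

__all__ = ["REDUCED_SCALE", "lmm_recovery", "lmm_null_rejections",
           "connectivity_recovery", "fdr_null_experiment"]

# reduced-scale validation conditions: 8 subjects per group, 8 channels,
# 12 trials per condition; moderate random-effect spread around a unit
# residual s.d.
REDUCED_SCALE = {
    "n_per_group": 8,
    "n_channels": 8,
    "n_trials_per_cond": 12,
    "subject_re_sd": {"1": 0.3, "stim": 0.1, "ph2": 0.1},
    "channel_re_sd": {"1": 0.2, "stim": 0.1, AMPLITUDE_TERM: 0.1},
    "resid_sd": 1.0,
}


def _study(effect: float, seed: int):
    return simulate_feature_table(
        n_per_group=REDUCED_SCALE["n_per_group"],
        n_channels=REDUCED_SCALE["n_channels"],
        n_trials_per_cond=REDUCED_SCALE["n_trials_per_cond"],
        effects={AMPLITUDE_TERM: effect} if effect else {},
        subject_re_sd=REDUCED_SCALE["subject_re_sd"],
        channel_re_sd=REDUCED_SCALE["channel_re_sd"],
        resid_sd=REDUCED_SCALE["resid_sd"],
        seed=seed)


def lmm_recovery(effect: float = 0.3, n_reps: int = 100,
                 seed: int = 0, alpha: float = 0.05) -> dict:
    """Fit the full trial model to ``n_reps`` simulated studies with a
    planted three-way amplitude effect; report the mean estimate, its
    relative error, and the Satterthwaite CI coverage of the truth."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, n_reps)
    est, covered = [], []
    for s in seeds:
        res = TrialLMM(_study(effect, int(s))).fit()
        est.append(float(res.fe_params[AMPLITUDE_TERM]))
        lo, hi = res.core.conf_int(AMPLITUDE_TERM, alpha)
        covered.append(lo <= effect <= hi)
    mean_est = float(np.mean(est))
    return {
        "effect": effect,
        "n_reps": n_reps,
        "mean_estimate": mean_est,
        "relative_error": abs(mean_est - effect) / abs(effect),
        "coverage": float(np.mean(covered)),
        "sd_estimate": float(np.std(est, ddof=1)),
    }


def lmm_null_rejections(n_reps: int = 200, seed: int = 1,
                        alpha: float = 0.05) -> dict:
    """Type-I error of the three-way test under the null at reduced scale."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, n_reps)
    rej = []
    for s in seeds:
        res = TrialLMM(_study(0.0, int(s))).fit()
        rej.append(res.test_term(AMPLITUDE_TERM)["p"] < alpha)
    return {"n_reps": n_reps, "rejection_rate": float(np.mean(rej))}


def connectivity_recovery(effect: float = 0.2, n_reps: int = 100,
                          seed: int = 2) -> dict:
    """Bias of the group1 x phase2 estimate in the reduced connectivity
    model over simulated pair tables."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, n_reps)
    est = []
    for s in seeds:
        tab = simulate_pair_table(
            n_per_group=8, n_pairs=10,
            effects={CONNECTIVITY_TERM: effect},
            subject_re_sd={"1": 0.15, "ph2": 0.05},
            pair_re_sd={"1": 0.1, CONNECTIVITY_TERM: 0.05},
            resid_sd=0.3, seed=int(s))
        est.append(float(ConnectivityLMM(tab).fit()
                         .fe_params[CONNECTIVITY_TERM]))
    mean_est = float(np.mean(est))
    return {
        "effect": effect,
        "n_reps": n_reps,
        "mean_estimate": mean_est,
        "relative_bias": (mean_est - effect) / effect,
    }


def fdr_null_experiment(n_reps: int = 200, n_null: int = 40, n_sig: int = 10,
                        q_star: float = 0.15, seed: int = 3) -> dict:
    """Empirical false-discovery proportion of the BH step-up on mixtures of
    independent uniform nulls and strong signals."""
    rng = np.random.default_rng(seed)
    fdp = []
    for _ in range(n_reps):
        p = np.concatenate([rng.uniform(size=n_null),
                            rng.uniform(size=n_sig) * 1e-5])
        res = bh_fdr(p, q_star=q_star)
        n_sel = int(res.selected.sum())
        fdp.append(res.selected[:n_null].sum() / n_sel if n_sel else 0.0)
    return {"n_reps": n_reps, "q_star": q_star,
            "empirical_fdr": float(np.mean(fdp))}
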