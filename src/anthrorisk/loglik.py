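"""Weighted Efron partial log-likelihood under left truncation.

Used for penalty selection in the spline fits (AIC needs the
*unpenalized* likelihood at the penalized solution) and as an
independent cross-check of the fitting library's reported likelihoods.
A subject is at risk at age t when entry < t <= exit; tied event ages
are handled by Efron's approximation with case weights.
"""
from __future__ import annotations

import numpy as np


def efron_partial_loglik(
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    eta: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Efron-approximated Cox partial log-likelihood of linear predictor
    ``eta`` with delayed entry and optional case weights."""
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event, bool)
    eta = np.asarray(eta, float)
    w = np.ones_like(eta) if weights is None else np.asarray(weights, float)

    # numeric guard: shift eta so exp() stays in range (invariant under shift)
    shift = eta.max()
    r = w * np.exp(eta - shift)

    exit_order = np.argsort(exit_)
    exit_sorted = exit_[exit_order]
    r_by_exit_suffix = np.concatenate([np.cumsum(r[exit_order][::-1])[::-1], [0.0]])
    entry_order = np.argsort(entry)
    entry_sorted = entry[entry_order]
    r_by_entry_suffix = np.concatenate([np.cumsum(r[entry_order][::-1])[::-1], [0.0]])

    def risk_sum(t: float) -> float:
        # sum of r over {exit >= t} minus over {entry >= t}  (entry < exit)
        i = np.searchsorted(exit_sorted, t, side="left")
        j = np.searchsorted(entry_sorted, t, side="left")
        return r_by_exit_suffix[i] - r_by_entry_suffix[j]

    ll = 0.0
    event_times = np.unique(exit_[event])
    for t in event_times:
        d_mask = event & (exit_ == t)
        m = int(d_mask.sum())
        wd = w[d_mask]
        ll += float(np.sum(wd * (eta[d_mask] - shift)))
        s_risk = risk_sum(t)
        s_tied = float(r[d_mask].sum())
        wbar = float(wd.sum()) / m
        ell = np.arange(m) / m
        ll -= wbar * float(np.sum(np.log(s_risk - ell * s_tied)))
    return ll
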