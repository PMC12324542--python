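"""Orientation-tuning estimation and circular geometry.

Orientation lives on a 180-degree circle: a grating at 0 deg and 180 deg
is the same stimulus, so all angular arithmetic doubles the angle inside
trigonometric functions.  The preferred orientation of a neuron is the
angle of the complex vector sum of its mean responses,

    theta_pref = (1/2) * arg( sum_theta R(theta) * exp(2i*theta) ),

and the orientation selectivity index (OSI) is the magnitude of the
normalized vector sum,

    OSI = | sum_theta R(theta) * exp(2i*theta) | / sum_theta |R(theta)|,

ranging from 0 (untuned) to 1 (perfectly selective).  Negative responses
(possible after baseline subtraction of z-scores) enter the complex sum
as-is; only the denominator takes absolute values.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import EnsembleSpec, SessionBundle
from . import stats as _stats

#: Neurons must exceed this OSI to enter tuning-dependent analyses.
CELL_OSI_THRESHOLD = 0.4
#: Ensembles must exceed this OSI to enter tuning-dependent analyses.
ENSEMBLE_OSI_THRESHOLD = 0.3

_DEGENERATE_TOL = 1e-12


def angular_difference(a, b):
    """Smallest angle between two orientations, in degrees on [0, 90].

    Symmetric and 180-degree periodic in both arguments.
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def orientation_vector_sum(responses, orientations) -> complex:
    """Complex vector sum ``sum R(theta) exp(2i theta)`` (theta in radians)."""
    R = np.asarray(responses, dtype=float)
    th = np.radians(np.asarray(orientations, dtype=float))
    if R.shape[-1] != th.shape[-1]:
        raise ValueError("responses and orientations must have equal length")
    if len(np.unique(th)) < 2:
        raise ValueError("need responses at >= 2 distinct orientations")
    return complex(np.sum(R * np.exp(2j * th)))


def preferred_orientation(responses, orientations) -> tuple[float, bool]:
    """Vector-sum preferred orientation in degrees on [0, 180).

    Returns ``(theta_pref, is_degenerate)``; a zero-magnitude vector sum
    (perfectly untuned cell) maps to the convention value 0 deg with the
    degenerate flag set.
    """
    z = orientation_vector_sum(responses, orientations)
    if abs(z) <= _DEGENERATE_TOL:
        return 0.0, True
    return float(np.degrees(np.angle(z)) / 2.0 % 180.0), False


def osi(responses, orientations) -> tuple[float, bool]:
    """Orientation selectivity index in [0, 1]; flags the all-zero case."""
    R = np.asarray(responses, dtype=float)
    denom = np.sum(np.abs(R))
    if denom <= _DEGENERATE_TOL:
        return 0.0, True
    z = orientation_vector_sum(R, orientations)
    return float(min(abs(z) / denom, 1.0)), False


def estimate_tuning(
    session: SessionBundle,
    orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
    osi_threshold: float = CELL_OSI_THRESHOLD,
    visual_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-neuron tuning table from the visual trials of a session.

    Mean responses per orientation are taken over stim_ON visual trials
    without photostimulation (or over ``visual_mask`` if given).  Columns:
    ``neuron_id``, ``theta_pref``, ``osi``, ``is_tuned`` (strict
    ``osi > osi_threshold``), ``degenerate_flag`` and one
    ``resp_<theta>`` column per orientation.
    """
    rows = []
    for j, neuron in enumerate(session.neurons):
        R = []
        for theta in orientations:
            mask = session.trial_mask(vis_orientation=theta, stim_ensemble=None, epoch="stim_ON")
            if visual_mask is not None:
                mask = mask & visual_mask
            R.append(session.responses[mask, j].mean() if mask.any() else 0.0)
        theta_pref, deg_p = preferred_orientation(R, orientations)
        sel, deg_o = osi(R, orientations)
        degenerate = deg_p or deg_o
        rows.append(
            {
                "neuron_id": neuron.neuron_id,
                "theta_pref": theta_pref,
                "osi": sel,
                "is_tuned": (not degenerate) and sel > osi_threshold,
                "degenerate_flag": degenerate,
                **{f"resp_{int(t)}": R[k] for k, t in enumerate(orientations)},
            }
        )
    return pd.DataFrame(rows)


def select_tuned(
    table: pd.DataFrame,
    cell_threshold: float = CELL_OSI_THRESHOLD,
) -> np.ndarray:
    """Neuron ids passing the strict OSI filter (``osi > threshold``)."""
    keep = (table["osi"].to_numpy() > cell_threshold) & ~table["degenerate_flag"].to_numpy()
    return table.loc[keep, "neuron_id"].to_numpy()


def ensemble_tuning(member_responses, orientations=(0.0, 45.0, 90.0, 135.0)) -> tuple[float, float]:
    """Tuning of an ensemble: vector-sum statistics of the across-member
    mean response vector.  ``member_responses`` is [n_members x n_orient].
    """
    R = np.asarray(member_responses, dtype=float)
    if R.ndim == 1:
        R = R[None, :]
    mean_R = R.mean(axis=0)
    theta, _ = preferred_orientation(mean_R, orientations)
    sel, _ = osi(mean_R, orientations)
    return theta, sel


def qualifying_ensembles(
    ensembles: Sequence[EnsembleSpec],
    osi_threshold: float = ENSEMBLE_OSI_THRESHOLD,
) -> list[EnsembleSpec]:
    """Ensembles passing the strict ensemble-level OSI filter."""
    return [e for e in ensembles if e.osi > osi_threshold]


def tuning_dependent_response_curve(
    session: SessionBundle,
    ensembles: Sequence[EnsembleSpec],
    tuning_table: pd.DataFrame,
    cell_type: str = "PC",
    bins: Sequence[float] = (0.0, 45.0, 90.0),
    n_bootstrap: int = 2000,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, _stats.TestResult | None]:
    """Photostimulation effect vs tuning offset from the stimulated ensemble.

    For every (non-targeted, tuned cell of ``cell_type``) x (qualifying
    ensemble) pair, the effect is that cell's mean response over the
    ensemble's stim_ON trials, and the pair is binned by the angular
    difference between the cell's and the ensemble's preferred
    orientation (discrete offsets {0, 45, 90} in the 4-orientation
    design; the nearest bin wins).  Returns a per-bin table (mean,
    bootstrap 95% CI, pair count; empty bins report NaN) and the
    Spearman rank correlation of effect vs offset over all pairs
    (``None`` when undefined).
    """
    ens_ok = qualifying_ensembles(ensembles)
    targeted = {n.neuron_id for n in session.neurons if n.is_targeted}
    cells = tuning_table.merge(session.neuron_frame(), on="neuron_id")
    cells = cells[
        cells["is_tuned"] & (cells["cell_type"] == cell_type) & ~cells["neuron_id"].isin(targeted)
    ]

    offsets, effects = [], []
    for ens in ens_ok:
        mask = session.trial_mask(stim_ensemble=ens.ensemble_id, epoch="stim_ON")
        if not mask.any():
            continue
        cols = session.column_of(cells["neuron_id"])
        eff = session.responses[np.ix_(mask, cols)].mean(axis=0)
        doff = angular_difference(cells["theta_pref"].to_numpy(), ens.pref_orientation)
        offsets.append(doff)
        effects.append(eff)
    if offsets:
        offsets = np.concatenate(offsets)
        effects = np.concatenate(effects)
    else:
        offsets = np.array([])
        effects = np.array([])

    bins = np.asarray(bins, dtype=float)
    if offsets.size:
        bin_idx = np.argmin(np.abs(offsets[:, None] - bins[None, :]), axis=1)
    else:
        bin_idx = np.array([], dtype=int)
    rows = []
    for k, b in enumerate(bins):
        vals = effects[bin_idx == k] if offsets.size else np.array([])
        if vals.size == 0:
            rows.append({"delta_theta": b, "mean": np.nan, "ci_low": np.nan, "ci_high": np.nan, "n": 0})
            continue
        if vals.size >= 2:
            lo, hi = _stats.bootstrap_ci(vals, n_resamples=n_bootstrap, seed=seed)
        else:
            lo = hi = float(vals[0])
        rows.append(
            {"delta_theta": b, "mean": float(vals.mean()), "ci_low": lo, "ci_high": hi, "n": int(vals.size)}
        )
    curve = pd.DataFrame(rows)

    corr = None
    if offsets.size >= 3 and np.unique(offsets).size > 1 and np.unique(effects).size > 1:
        corr = _stats.spearman(offsets, effects)
    return curve, corr
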