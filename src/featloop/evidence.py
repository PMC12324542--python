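"""Decoder-evidence projections and explaining-away analytics.

*Evidence* for an orientation class is the dot product between a
population activity vector and that class's decoder weight vector
(intercepts excluded — they cancel in every ON-OFF difference).  The
*explaining-away index* is the reduction, under photostimulation, of
the evidence for the two orientations flanking (+/-45 deg) the visual
stimulus, relative to visual-only trials: positive values mean
suppression of competing interpretations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import EnsembleSpec, SessionBundle
from .decoding import (
    DecoderResults,
    OrientationDecoder,
    _photoactivation_zone,
    alignment_bin,
)
from .tuning import angular_difference


def evidence_projection(results: DecoderResults, activity) -> np.ndarray:
    """Per-class evidence ``w_c . x`` for one activity vector or a stack.

    ``activity`` must be aligned to ``results.feature_neuron_ids``;
    use :meth:`DecoderResults.features_from` for session rows.  Returns
    shape ``[n_classes]`` for one vector, ``[n_rows, n_classes]`` for a
    matrix.  Both entry points of the analysis use this projection:
    trial-averaged vectors for ensemble-level curves, single-trial rows
    for the explaining-away index.
    """
    x = np.asarray(activity, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != len(results.feature_neuron_ids):
        raise ValueError(
            f"feature mismatch: got {x.shape[1]} columns, expected "
            f"{len(results.feature_neuron_ids)}"
        )
    ev = x @ results.weights.T
    return ev[0] if single else ev


def _snap(theta: float, classes: Sequence[float]) -> float:
    classes = np.asarray(classes, dtype=float)
    return float(classes[np.argmin(angular_difference(classes, theta))])


def evidence_by_offset(
    evidence,
    ensemble_pref: float,
    class_orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
) -> pd.Series:
    """Re-index a 4-class evidence vector by tuning offset from the
    ensemble preference (snapped to the class grid); the two classes at
    45 deg offset are averaged."""
    ev = np.asarray(evidence, dtype=float)
    if ev.shape[-1] != len(class_orientations):
        raise ValueError("evidence length must match the class count")
    if ev.ndim == 2:
        ev = ev.mean(axis=0)
    pref = _snap(ensemble_pref, class_orientations)
    offs = angular_difference(np.asarray(class_orientations, float), pref)
    out = {}
    for b in (0.0, 45.0, 90.0):
        sel = offs == b
        out[b] = float(ev[sel].mean()) if sel.any() else np.nan
    return pd.Series(out, name="evidence")


def _flank_and_correct(classes: np.ndarray) -> dict[float, tuple[np.ndarray, int]]:
    table = {}
    for theta in classes:
        offs = angular_difference(classes, theta)
        table[float(theta)] = (np.flatnonzero(offs == 45.0), int(np.argmin(offs)))
    return table


def explaining_away(
    ev_on: np.ndarray,
    vis_on,
    ev_off: np.ndarray,
    vis_off,
    ensemble_pref: float,
    class_orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
) -> pd.DataFrame:
    """Per-ON-trial explaining-away index, grouped by stimulus/ensemble
    alignment.

    ``ev_on``/``ev_off`` are single-trial evidence matrices for
    interleaved photostim-ON and visual-only (OFF) trials, with the
    presented orientation per trial in ``vis_on``/``vis_off``.  For each
    ON trial the index is ``OFF_flank - ON_flank`` where the flanking
    evidence is the mean over the two classes 45 deg from the stimulus
    and the OFF reference is the mean over same-stimulus OFF trials.
    The change in correct-orientation evidence is reported alongside.
    """
    classes = np.asarray(class_orientations, dtype=float)
    ev_on = np.atleast_2d(ev_on)
    ev_off = np.atleast_2d(ev_off)
    vis_on = np.asarray(vis_on, dtype=float)
    vis_off = np.asarray(vis_off, dtype=float)
    lut = _flank_and_correct(classes)

    off_flank, off_correct = {}, {}
    for theta in classes:
        sel = np.array([_snap(v, classes) == theta for v in vis_off])
        if not sel.any():
            continue
        flanks, correct = lut[float(theta)]
        off_flank[float(theta)] = float(ev_off[sel][:, flanks].mean())
        off_correct[float(theta)] = float(ev_off[sel][:, correct].mean())

    rows = []
    for i in range(ev_on.shape[0]):
        theta = _snap(vis_on[i], classes)
        if theta not in off_flank:
            continue
        flanks, correct = lut[theta]
        rows.append(
            {
                "vis_orientation": theta,
                "explaining_away_index": off_flank[theta] - float(ev_on[i, flanks].mean()),
                "correct_evidence_change": off_correct[theta] - float(ev_on[i, correct]),
                "delta_vis_ensemble": float(angular_difference(theta, ensemble_pref)),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["alignment"] = alignment_bin(table["delta_vis_ensemble"].to_numpy())
    return table


def explaining_away_session(
    session: SessionBundle,
    results: DecoderResults,
    ensemble: EnsembleSpec,
    class_orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
) -> pd.DataFrame:
    """Run the explaining-away analysis on a session with interleaved
    visual trials with and without ensemble photostimulation (training
    block excluded)."""
    test = ~np.array([t.train_block for t in session.trials])
    vis = np.array([t.vis_orientation is not None for t in session.trials])
    stim = np.array([t.stim_ensemble is not None for t in session.trials])
    on_mask = test & vis & stim
    off_mask = test & vis & ~stim
    ev_on = evidence_projection(results, results.features_from(session, on_mask))
    ev_off = evidence_projection(results, results.features_from(session, off_mask))
    vis_all = np.array(
        [np.nan if t.vis_orientation is None else t.vis_orientation for t in session.trials]
    )
    return explaining_away(
        ev_on, vis_all[on_mask], ev_off, vis_all[off_mask],
        ensemble.pref_orientation, class_orientations,
    )


# ---------------------------------------------------------------------------
# Tuning-curve normalization for ON/OFF comparisons
# ---------------------------------------------------------------------------

@dataclass
class NormalizedTuningCurves:
    """Offset-corrected, OFF-peak-normalized tuning curves.

    ``off``/``on`` are ``[n_cells x n_orientations]``; for every kept
    cell the OFF curve peaks at exactly 1 and is non-negative.
    ``offset_applied`` records the additive correction (0 when the raw
    OFF minimum was already non-negative), ``peak_off`` the divisor.
    ``kept`` flags cells whose corrected OFF peak was positive; excluded
    cells carry NaN rows.
    """

    off: np.ndarray
    on: np.ndarray
    offset_applied: np.ndarray
    peak_off: np.ndarray
    kept: np.ndarray


def normalize_tuning_curves(off_responses, on_responses) -> NormalizedTuningCurves:
    """Normalize per-cell tuning curves for ON/OFF comparison.

    The offset correction is computed from the unperturbed (OFF)
    condition only — if min(OFF) < 0 its absolute value is added to both
    conditions — and both are divided by the corrected OFF peak, so an
    ON curve identical to OFF also peaks at 1.  Flat-at-zero cells are
    excluded with a warning.
    """
    off = np.atleast_2d(np.asarray(off_responses, dtype=float)).copy()
    on = np.atleast_2d(np.asarray(on_responses, dtype=float)).copy()
    if off.shape != on.shape:
        raise ValueError("OFF and ON response matrices must have the same shape")
    offset = np.maximum(0.0, -off.min(axis=1))
    off += offset[:, None]
    on += offset[:, None]
    peak = off.max(axis=1)
    kept = peak > 0
    if not kept.all():
        warnings.warn(f"excluding {int((~kept).sum())} flat-at-zero cells from normalization")
    off_n = np.full_like(off, np.nan)
    on_n = np.full_like(on, np.nan)
    off_n[kept] = off[kept] / peak[kept, None]
    on_n[kept] = on[kept] / peak[kept, None]
    return NormalizedTuningCurves(off_n, on_n, offset, peak, kept)


def cosine_similarity(u, v) -> float:
    """``u.v / (|u||v|)``; undefined (raises) for a zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def population_similarity_ratio(
    on_vectors: Mapping[float, np.ndarray],
    off_vectors: Mapping[float, np.ndarray],
    ensemble_pref: float,
    class_orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
) -> pd.DataFrame:
    """Flanking-vs-matching population similarity under photostimulation.

    For each stimulus orientation theta the ratio is
    ``mean_flank cos(ON_theta, OFF_theta+/-45) / cos(ON_theta, OFF_theta)``,
    computed over decoder-informative neurons, and grouped by the
    alignment between theta and the stimulated ensemble.  Degenerate
    (zero) denominators drop the orientation with a warning.
    """
    classes = np.asarray(class_orientations, dtype=float)
    rows = []
    for theta in classes:
        t = float(theta)
        if t not in on_vectors or t not in off_vectors:
            continue
        flanks = classes[angular_difference(classes, t) == 45.0]
        flank_sims = [
            cosine_similarity(on_vectors[t], off_vectors[float(f)])
            for f in flanks
            if float(f) in off_vectors
        ]
        if not flank_sims:
            continue
        denom = cosine_similarity(on_vectors[t], off_vectors[t])
        if abs(denom) < 1e-12:
            warnings.warn(f"degenerate matching similarity at {t} deg; excluded")
            continue
        rows.append(
            {
                "vis_orientation": t,
                "ratio": float(np.mean(flank_sims)) / denom,
                "delta_vis_ensemble": float(angular_difference(t, ensemble_pref)),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["alignment"] = alignment_bin(table["delta_vis_ensemble"].to_numpy())
    return table


def subgroup_evidence(
    session: SessionBundle,
    ensemble: EnsembleSpec,
    tuning_table: pd.DataFrame,
    penalty: float | str = 1.0,
    seed: int = 0,
    class_orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
) -> dict[str, pd.DataFrame]:
    """Explaining-away analysis restricted to co-tuned or anti-tuned PCs.

    Subgroups are tuned, non-targeted PCs whose preference offset from
    the ensemble falls in the 0-deg bin (co-tuned, offset < 22.5) or the
    90-deg bin (anti-tuned, offset > 67.5).  An independent decoder is
    trained per subgroup and the full explaining-away pipeline rerun;
    subgroups too small to train are skipped with a warning.
    """
    excluded = {n.neuron_id for n in session.neurons if n.is_targeted}
    excluded |= _photoactivation_zone(session, 30.0)
    merged = tuning_table.merge(session.neuron_frame(), on="neuron_id")
    tuned_pc = merged[
        merged["is_tuned"] & (merged["cell_type"] == "PC") & ~merged["neuron_id"].isin(excluded)
    ]
    offs = angular_difference(tuned_pc["theta_pref"].to_numpy(), ensemble.pref_orientation)
    groups = {
        "co_tuned": tuned_pc.loc[offs < 22.5, "neuron_id"].tolist(),
        "anti_tuned": tuned_pc.loc[offs > 67.5, "neuron_id"].tolist(),
    }
    out: dict[str, pd.DataFrame] = {}
    for name, ids in groups.items():
        if len(ids) < 2:
            warnings.warn(f"subgroup {name!r} too small to train a decoder; skipped")
            continue
        try:
            res = OrientationDecoder(
                session, penalty=penalty, feature_neuron_ids=ids,
                orientations=class_orientations,
            ).fit(seed=seed)
        except ValueError as e:
            warnings.warn(f"subgroup {name!r} skipped: {e}")
            continue
        out[name] = explaining_away_session(session, res, ensemble, class_orientations)
    return out
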