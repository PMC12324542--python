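"""Decoder-based assay of visual-like activity.

A sparse linear multi-class classifier is trained to predict grating
orientation from the visual-trial responses of non-targeted pyramidal
cells (all of them, regardless of tuning), then probed with
photostimulation trials.  The headline statistic is the ΔPrediction:
the angular difference between the decoded orientation and the
stimulated ensemble's preference, minus the 45-degree four-class chance
level, so that negative values mean completion (co-tuned bias) and
positive values mean suppression (anti-tuned bias).

The module follows the Model/Results convention:
:class:`OrientationDecoder` holds the training design; ``fit()`` returns
a :class:`DecoderResults` carrying weights, intercepts, the feature
neuron set, cross-validated accuracy and prediction entry points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC

from .data_model import SessionBundle
from .tuning import angular_difference
from . import stats as _stats

#: Weights smaller than this (absolute) count as zero after L1 training.
NONZERO_WEIGHT_TOL = 1e-10
#: Default radius (micrometres) of the photoactivation zone excluded
#: around every target; an assumption, not a measured value.
DEFAULT_EXCLUSION_RADIUS_UM = 30.0

_C_GRID = (0.01, 0.1, 1.0, 10.0)


def _photoactivation_zone(session: SessionBundle, radius_um: float) -> set[int]:
    """Neuron ids within ``radius_um`` of any targeted neuron's centroid."""
    targets = np.array([n.centroid for n in session.neurons if n.is_targeted])
    if targets.size == 0:
        return set()
    zone = set()
    for n in session.neurons:
        d = np.linalg.norm(targets - np.asarray(n.centroid), axis=1)
        if d.min() <= radius_um:
            zone.add(n.neuron_id)
    return zone


class OrientationDecoder:
    """L1-sparse linear orientation classifier over non-targeted cells.

    Parameters
    ----------
    session
        Training session.  By default the training trials are the
        visual stim_ON trials without photostimulation; if any trial is
        flagged ``train_block`` the independent training block is used
        instead.
    cell_type
        Feature cell type (default pyramidal cells).
    exclusion_radius_um
        Photoactivation-zone radius: neurons within this distance of
        any target are excluded from the feature set along with the
        targets themselves.
    penalty
        L1 penalty strength ``C`` of the underlying one-vs-rest linear
        SVC, or ``"auto"`` to pick it by stratified 5-fold
        cross-validation on the training trials.
    """

    def __init__(
        self,
        session: SessionBundle,
        cell_type: str = "PC",
        exclusion_radius_um: float = DEFAULT_EXCLUSION_RADIUS_UM,
        penalty: float | str = "auto",
        feature_neuron_ids: Sequence[int] | None = None,
        orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
        train_mask: np.ndarray | None = None,
    ) -> None:
        self.session = session
        self.orientations = tuple(float(t) for t in orientations)
        self.penalty = penalty

        targeted = {n.neuron_id for n in session.neurons if n.is_targeted}
        zone = _photoactivation_zone(session, exclusion_radius_um)
        if feature_neuron_ids is None:
            feature_neuron_ids = [
                n.neuron_id
                for n in session.neurons
                if n.cell_type == cell_type
                and not n.is_targeted
                and n.neuron_id not in zone
            ]
        feature_neuron_ids = list(feature_neuron_ids)
        # leakage guard: the decoder must never see targeted activity
        leak = (set(feature_neuron_ids) & targeted) | (set(feature_neuron_ids) & zone)
        if leak:
            raise ValueError(
                f"feature set leaks {len(leak)} targeted/photoactivation-zone "
                f"neurons (e.g. {sorted(leak)[:5]})"
            )
        if not feature_neuron_ids:
            raise ValueError("empty feature set after target/zone exclusion")
        self.feature_neuron_ids = feature_neuron_ids

        if train_mask is None:
            train_mask = session.trial_mask(stim_ensemble=None, epoch="stim_ON")
            has_block = any(t.train_block for t in session.trials)
            if has_block:
                train_mask &= np.array([t.train_block for t in session.trials])
            train_mask &= np.array([t.vis_orientation is not None for t in session.trials])
        self.train_mask = np.asarray(train_mask, dtype=bool)

        labels = np.array(
            [np.nan if t.vis_orientation is None else t.vis_orientation for t in session.trials]
        )[self.train_mask]
        for theta in self.orientations:
            if np.sum(labels == theta) < 2:
                raise ValueError(f"class {theta} deg has fewer than 2 training trials")
        self._y = labels
        cols = session.column_of(self.feature_neuron_ids)
        self._X = session.responses[self.train_mask][:, cols]

    def fit(self, seed: int = 0) -> "DecoderResults":
        """Train; returns a results object.  Deterministic given data,
        penalty and seed."""
        if self.penalty == "auto":
            C = self._select_penalty(seed)
        else:
            C = float(self.penalty)
        clf = LinearSVC(penalty="l1", dual=False, C=C, max_iter=20_000, random_state=seed)
        clf.fit(self._X, self._y)
        cv_acc = self._cv_accuracy(C, seed)
        order = np.argsort(clf.classes_)
        return DecoderResults(
            class_orientations=tuple(float(c) for c in clf.classes_[order]),
            weights=clf.coef_[order],
            intercepts=clf.intercept_[order],
            feature_neuron_ids=list(self.feature_neuron_ids),
            sparsity_penalty=C,
            cv_accuracy=cv_acc,
            n_train=int(self._y.size),
        )

    # -- internals -------------------------------------------------------
    def _cv(self, seed: int) -> StratifiedKFold:
        min_class = min(int(np.sum(self._y == t)) for t in self.orientations)
        return StratifiedKFold(n_splits=min(5, min_class), shuffle=True, random_state=seed)

    def _cv_accuracy(self, C: float, seed: int) -> float:
        clf = LinearSVC(penalty="l1", dual=False, C=C, max_iter=20_000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(cross_val_score(clf, self._X, self._y, cv=self._cv(seed)).mean())

    def _select_penalty(self, seed: int) -> float:
        scores = [self._cv_accuracy(C, seed) for C in _C_GRID]
        return float(_C_GRID[int(np.argmax(scores))])


@dataclass
class DecoderResults:
    """Fitted decoder: per-class weight vectors and intercepts over a
    declared, leakage-guarded feature-neuron set."""

    class_orientations: tuple[float, ...]
    weights: np.ndarray
    intercepts: np.ndarray
    feature_neuron_ids: list[int]
    sparsity_penalty: float
    cv_accuracy: float | None = None
    n_train: int | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.weights.shape != (len(self.class_orientations), len(self.feature_neuron_ids)):
            raise ValueError("weights shape inconsistent with classes/features")

    # -- prediction ------------------------------------------------------
    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_neuron_ids):
            raise ValueError(
                f"feature mismatch: got {X.shape[1]} columns, "
                f"expected {len(self.feature_neuron_ids)}"
            )
        return X @ self.weights.T + self.intercepts

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted orientation per row; exact score ties break toward
        the lowest class orientation (argmax-first over ascending
        classes)."""
        scores = self.decision_scores(X)
        return np.asarray(self.class_orientations)[np.argmax(scores, axis=1)]

    def features_from(self, session: SessionBundle, trial_mask: np.ndarray | None = None) -> np.ndarray:
        """Response rows of another session aligned to the feature set."""
        cols = session.column_of(self.feature_neuron_ids)
        rows = session.responses if trial_mask is None else session.responses[trial_mask]
        return rows[:, cols]

    def predict_session(self, session: SessionBundle, trial_mask: np.ndarray | None = None) -> np.ndarray:
        return self.predict(self.features_from(session, trial_mask))

    def decoder_informative(self, tol: float = NONZERO_WEIGHT_TOL) -> list[int]:
        """Neuron ids retaining any nonzero weight after L1 training."""
        keep = np.any(np.abs(self.weights) > tol, axis=0)
        return [nid for nid, k in zip(self.feature_neuron_ids, keep) if k]

    # -- serialization ---------------------------------------------------
    def to_json(self, path) -> None:
        """Write the fitted decoder (weights, intercepts, feature ids) to JSON."""
        import json
        from pathlib import Path

        payload = {
            "class_orientations": list(self.class_orientations),
            "weights": self.weights.tolist(),
            "intercepts": self.intercepts.tolist(),
            "feature_neuron_ids": [int(i) for i in self.feature_neuron_ids],
            "sparsity_penalty": self.sparsity_penalty,
            "cv_accuracy": self.cv_accuracy,
            "n_train": self.n_train,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "DecoderResults":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        return cls(
            class_orientations=tuple(payload["class_orientations"]),
            weights=np.asarray(payload["weights"], dtype=float),
            intercepts=np.asarray(payload["intercepts"], dtype=float),
            feature_neuron_ids=list(payload["feature_neuron_ids"]),
            sparsity_penalty=float(payload["sparsity_penalty"]),
            cv_accuracy=payload.get("cv_accuracy"),
            n_train=payload.get("n_train"),
        )

    def summary(self) -> str:
        nz = len(self.decoder_informative())
        lines = [
            "Orientation decoder (one-vs-rest linear SVC, L1 penalty)",
            f"  classes:            {self.class_orientations} deg",
            f"  features:           {len(self.feature_neuron_ids)} non-targeted neurons",
            f"  nonzero-weight set: {nz} decoder-informative neurons",
            f"  penalty C:          {self.sparsity_penalty:g}",
        ]
        if self.n_train is not None:
            lines.append(f"  training trials:    {self.n_train}")
        if self.cv_accuracy is not None:
            lines.append(f"  CV accuracy:        {self.cv_accuracy:.3f}")
        return "\n".join(lines)


def train_decoder(
    session: SessionBundle,
    penalty: float | str = "auto",
    seed: int = 0,
    **kwargs,
) -> DecoderResults:
    """Convenience wrapper: build an :class:`OrientationDecoder` and fit it."""
    return OrientationDecoder(session, penalty=penalty, **kwargs).fit(seed=seed)


# ---------------------------------------------------------------------------
# ΔPrediction and decoder error
# ---------------------------------------------------------------------------

CHANCE_ERROR_DEG = 45.0


@dataclass(frozen=True)
class DeltaPrediction:
    """Per-trial ΔPrediction of one ensemble.

    ``raw`` is the angular error in [0, 90] between the decoded
    orientation and the ensemble preference; ``centered`` subtracts the
    45-degree four-class chance error, mapping to [-45, 45].
    """

    raw: np.ndarray
    centered: np.ndarray

    @property
    def mean_raw(self) -> float:
        return float(np.mean(self.raw))

    @property
    def mean_centered(self) -> float:
        return float(np.mean(self.centered))


def delta_prediction(predictions, ensemble_pref: float) -> DeltaPrediction:
    raw = angular_difference(np.asarray(predictions, dtype=float), ensemble_pref)
    return DeltaPrediction(raw=raw, centered=raw - CHANCE_ERROR_DEG)


def off_on_comparison(
    off_by_ensemble: Mapping[int, float],
    on_by_ensemble: Mapping[int, float],
) -> tuple[pd.DataFrame, _stats.TestResult]:
    """Paired per-ensemble comparison of centered ΔPrediction on
    baseline-OFF vs stimulation-ON trials; unpaired ensembles are
    dropped with a warning.  The paired test is normality-gated
    (paired t-test or Wilcoxon signed-rank)."""
    common = sorted(set(off_by_ensemble) & set(on_by_ensemble))
    missing = (set(off_by_ensemble) | set(on_by_ensemble)) - set(common)
    if missing:
        warnings.warn(f"excluding {len(missing)} unpaired ensembles: {sorted(missing)[:5]}")
    if not common:
        raise ValueError("no paired ensembles")
    off = np.array([off_by_ensemble[e] for e in common])
    on = np.array([on_by_ensemble[e] for e in common])
    table = pd.DataFrame(
        {"ensemble_id": common, "off": off, "on": on, "difference": on - off}
    )
    result = _stats.normality_gated_test(on, off, paired=True)
    return table, result


def decoder_error(predictions, true_orientations) -> np.ndarray:
    """Angular distance in degrees between decoded and true stimulus
    orientation ({0, 45, 90} in the four-class design)."""
    return angular_difference(np.asarray(predictions, float), np.asarray(true_orientations, float))


def percent_change(errors_on, errors_off) -> float:
    """Percent change in mean decoder error, ON relative to OFF."""
    mean_on = float(np.mean(errors_on))
    mean_off = float(np.mean(errors_off))
    if mean_off == 0.0:
        warnings.warn("mean OFF decoder error is zero; percent change undefined (NaN)")
        return float("nan")
    return 100.0 * (mean_on - mean_off) / mean_off


def alignment_bin(delta_theta) -> np.ndarray:
    """Bin an ensemble-vs-stimulus offset: aligned (< 45), boundary
    (= 45), misaligned (> 45); strict inequalities, boundary kept apart."""
    d = np.asarray(delta_theta, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.where(d < 45.0, "aligned", np.where(d > 45.0, "misaligned", "boundary"))
    return str(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# GMM modality check
# ---------------------------------------------------------------------------

def gmm_aic_select(
    values,
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
    n_bootstrap: int = 100,
    seed: int | None = 0,
) -> tuple[np.ndarray, int]:
    """Modality of a 1-D sample by AIC over Gaussian mixtures.

    For each bootstrap replicate (resampling the per-ensemble values
    with replacement), Gaussian mixtures with each component count in
    ``k_range`` are fit by EM and the min-AIC count selected.  Returns
    the per-replicate selections and the modal choice.  Non-converged
    fits are skipped with a warning.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    k_range = sorted(int(k) for k in k_range)
    if x.shape[0] < 10 * max(k_range):
        raise ValueError(f"need >= {10 * max(k_range)} samples for k_max={max(k_range)}")
    rng = np.random.default_rng(seed)
    selections = np.empty(n_bootstrap, dtype=int)
    for b in range(n_bootstrap):
        xb = x[rng.integers(0, x.shape[0], x.shape[0])]
        aics = {}
        for k in k_range:
            gm = GaussianMixture(n_components=k, random_state=int(rng.integers(2**31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(xb)
            if not gm.converged_:
                warnings.warn(f"EM did not converge for k={k} in replicate {b}; skipped")
                continue
            aics[k] = gm.aic(xb)
        selections[b] = min(aics, key=aics.get)
    counts = np.bincount(selections)
    return selections, int(np.argmax(counts))
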