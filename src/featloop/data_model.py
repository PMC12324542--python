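"""Core data types, session I/O and preprocessing.

A *session* is a trial-structured recording: a matrix of per-trial,
per-neuron scalar responses (z-scored, baseline-subtracted fluorescence),
plus neuron metadata (cell type, centroid, targeted flag) and trial
metadata (visual orientation, photostimulated ensemble, OFF/ON epoch).
Every downstream analysis consumes only :class:`SessionBundle` and
:class:`EnsembleSpec`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

CELL_TYPES = ("PC", "SST", "PV")
EPOCHS = ("baseline_OFF", "stim_ON")

#: Divisor floor for zero-variance traces in :func:`zscore_block`.
ZSCORE_EPS = 1e-12


@dataclass(frozen=True)
class NeuronRecord:
    """One recorded neuron (calcium source)."""

    neuron_id: int
    cell_type: str = "PC"
    centroid: tuple[float, float, float] = (0.0, 0.0, 0.0)
    is_targeted: bool = False
    plane: int = 0

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}, got {self.cell_type!r}")
        if not np.all(np.isfinite(self.centroid)):
            raise ValueError(f"neuron {self.neuron_id}: centroid must be finite")


@dataclass(frozen=True)
class TrialRecord:
    """One trial row.

    ``vis_orientation`` is the grating orientation in degrees on [0, 180)
    or ``None`` for trials without a visual stimulus.  ``stim_ensemble``
    is the photostimulated ensemble id or ``None``.  ``epoch`` says
    whether the response scalar was taken from the pre-stimulation
    baseline window (``baseline_OFF``) or the stimulation window
    (``stim_ON``).  ``train_block`` marks trials belonging to the
    independent visual-only block used for decoder training.
    """

    trial_id: int
    vis_orientation: float | None = None
    stim_ensemble: int | None = None
    epoch: str = "stim_ON"
    train_block: bool = False

    def __post_init__(self) -> None:
        if self.epoch not in EPOCHS:
            raise ValueError(f"epoch must be one of {EPOCHS}, got {self.epoch!r}")
        if self.vis_orientation is not None and not (0 <= self.vis_orientation < 180):
            raise ValueError(f"vis_orientation must lie in [0, 180), got {self.vis_orientation}")


@dataclass(frozen=True)
class EnsembleSpec:
    """A set of co-tuned targeted neurons jointly photostimulated."""

    ensemble_id: int
    member_ids: frozenset[int]
    pref_orientation: float
    osi: float

    def __post_init__(self) -> None:
        if len(self.member_ids) < 1:
            raise ValueError("ensemble must have at least one member")
        object.__setattr__(self, "member_ids", frozenset(int(m) for m in self.member_ids))

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class SessionBundle:
    """Trial-structured responses plus neuron and trial metadata.

    ``responses`` is ``[n_trials x n_neurons]`` float64; an optional
    ``traces`` array ``[n_trials x n_neurons x n_frames]`` carries the
    frame-resolved signal the scalars were reduced from.
    """

    responses: np.ndarray
    neurons: list[NeuronRecord]
    trials: list[TrialRecord]
    traces: np.ndarray | None = None
    frame_rate: float = 6.0

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.float64)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n_trials, n_neurons = self.responses.shape
        if len(self.neurons) != n_neurons:
            raise ValueError(
                f"responses has {n_neurons} neuron columns but {len(self.neurons)} NeuronRecords"
            )
        if len(self.trials) != n_trials:
            raise ValueError(
                f"responses has {n_trials} trial rows but {len(self.trials)} TrialRecords"
            )
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        ids = [n.neuron_id for n in self.neurons]
        if len(set(ids)) != len(ids):
            raise ValueError("neuron_id values must be unique within a session")
        if self.traces is not None and self.traces.shape[:2] != self.responses.shape:
            raise ValueError(
                f"traces shape {self.traces.shape} inconsistent with responses {self.responses.shape}"
            )

    # -- convenience views ----------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[1]

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.array([n.neuron_id for n in self.neurons])

    def neuron_frame(self) -> pd.DataFrame:
        rows = [
            {
                "neuron_id": n.neuron_id,
                "cell_type": n.cell_type,
                "x": n.centroid[0],
                "y": n.centroid[1],
                "z": n.centroid[2],
                "is_targeted": n.is_targeted,
                "plane": n.plane,
            }
            for n in self.neurons
        ]
        return pd.DataFrame(rows)

    def trial_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trial_id": t.trial_id,
                "vis_orientation": np.nan if t.vis_orientation is None else t.vis_orientation,
                "stim_ensemble": np.nan if t.stim_ensemble is None else t.stim_ensemble,
                "epoch": t.epoch,
                "train_block": t.train_block,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)

    def column_of(self, neuron_ids: Iterable[int]) -> np.ndarray:
        """Column indices of the given neuron ids, in the given order."""
        lookup = {n.neuron_id: j for j, n in enumerate(self.neurons)}
        try:
            return np.array([lookup[int(i)] for i in neuron_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"neuron_id {e.args[0]} not in session") from e

    def trial_mask(
        self,
        *,
        vis_orientation: float | None | str = "any",
        stim_ensemble: int | None | str = "any",
        epoch: str | None = None,
        train_block: bool | None = None,
    ) -> np.ndarray:
        """Boolean mask over trials; ``"any"`` leaves a field unconstrained."""
        mask = np.ones(self.n_trials, dtype=bool)
        for i, t in enumerate(self.trials):
            if vis_orientation != "any" and t.vis_orientation != vis_orientation:
                mask[i] = False
            elif stim_ensemble != "any" and t.stim_ensemble != stim_ensemble:
                mask[i] = False
            elif epoch is not None and t.epoch != epoch:
                mask[i] = False
            elif train_block is not None and t.train_block != train_block:
                mask[i] = False
        return mask


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _as_blocks(blocks: Sequence[tuple[int, int]], n_frames: int) -> list[tuple[int, int]]:
    out = []
    for start, stop in blocks:
        if not (0 <= start < stop <= n_frames):
            raise ValueError(f"block ({start}, {stop}) outside trace of length {n_frames}")
        if stop - start < 2:
            raise ValueError(f"block ({start}, {stop}) has fewer than 2 frames")
        out.append((int(start), int(stop)))
    return out


def zscore_block(traces: np.ndarray, blocks: Sequence[tuple[int, int]]) -> np.ndarray:
    """Z-score each neuron's trace independently within each experimental block.

    ``traces`` has frames on the last axis; ``blocks`` are half-open
    ``(start, stop)`` frame ranges (e.g. one per visual or holographic
    block).  Within each block, every neuron is centred and scaled to
    unit standard deviation (population sd, ddof=0).  A zero-variance
    trace gets an epsilon-floored divisor and a warning, yielding zeros
    rather than NaNs.
    """
    traces = np.asarray(traces, dtype=np.float64)
    out = traces.copy()
    for start, stop in _as_blocks(blocks, traces.shape[-1]):
        seg = traces[..., start:stop]
        mu = seg.mean(axis=-1, keepdims=True)
        sd = seg.std(axis=-1, keepdims=True)
        if np.any(sd <= ZSCORE_EPS):
            warnings.warn(
                "zero-variance trace within a block; divisor floored at "
                f"{ZSCORE_EPS:g} (output will be zero)",
                RuntimeWarning,
                stacklevel=2,
            )
        out[..., start:stop] = (seg - mu) / np.maximum(sd, ZSCORE_EPS)
    return out


def baseline_subtract(trace: np.ndarray, baseline: tuple[int, int]) -> np.ndarray:
    """Subtract the mean over the baseline frame window from each trace.

    After the call the mean of the output over the baseline window is 0
    for every neuron and trial (frames on the last axis).
    """
    trace = np.asarray(trace, dtype=np.float64)
    start, stop = baseline
    if not (0 <= start < stop <= trace.shape[-1]):
        raise ValueError(f"baseline window ({start}, {stop}) outside trace of length {trace.shape[-1]}")
    return trace - trace[..., start:stop].mean(axis=-1, keepdims=True)


def trial_response(trace: np.ndarray, window: tuple[int, int], reducer: str = "mean") -> np.ndarray:
    """Reduce a response trace to one scalar per neuron over the stimulus window.

    The default reducer is the mean of the evoked window; ``"peak"`` and
    ``"integral"`` are provided as configurable alternatives.
    """
    trace = np.asarray(trace, dtype=np.float64)
    start, stop = window
    if not (0 <= start < stop <= trace.shape[-1]):
        raise ValueError(f"stim window ({start}, {stop}) outside trace of length {trace.shape[-1]}")
    seg = trace[..., start:stop]
    if reducer == "mean":
        return seg.mean(axis=-1)
    if reducer == "peak":
        return seg.max(axis=-1)
    if reducer == "integral":
        return seg.sum(axis=-1)
    raise ValueError(f"unknown reducer {reducer!r}")


def seconds_to_frames(t: float, frame_rate: float) -> int:
    """Convert a duration in seconds to whole frames (floor)."""
    return int(np.floor(t * frame_rate))


@dataclass(frozen=True)
class TargetMatch:
    target_index: int
    neuron_id: int | None
    distance: float
    excluded: bool


def match_targets(
    target_coords: Sequence[Sequence[float]],
    roi_centroids: Sequence[Sequence[float]],
    roi_ids: Sequence[int] | None = None,
    max_dist: float = 12.0,
) -> list[TargetMatch]:
    """Assign each photostimulation target to its nearest ROI centroid.

    Matching is one-to-one and greedy by global distance: the closest
    remaining (target, centroid) pair is assigned first, so when two
    targets claim one centroid the nearer target wins and the loser
    rematches against the remaining centroids.  Assignments farther than
    ``max_dist`` micrometres are flagged excluded (distance recorded);
    targets left without a centroid are excluded with infinite distance.
    """
    targets = np.asarray(target_coords, dtype=float)
    rois = np.asarray(roi_centroids, dtype=float)
    if targets.size == 0 or rois.size == 0:
        raise ValueError("target and centroid lists must be nonempty")
    if roi_ids is None:
        roi_ids = list(range(len(rois)))
    dist = np.linalg.norm(targets[:, None, :] - rois[None, :, :], axis=-1)

    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None, kind="stable"), dist.shape))[0]
    assigned: dict[int, tuple[int, float]] = {}
    used_rois: set[int] = set()
    for ti, rj in order:
        if ti in assigned or rj in used_rois:
            continue
        assigned[int(ti)] = (int(rj), float(dist[ti, rj]))
        used_rois.add(int(rj))
        if len(assigned) == len(targets):
            break

    out = []
    for ti in range(len(targets)):
        if ti in assigned:
            rj, d = assigned[ti]
            out.append(TargetMatch(ti, int(roi_ids[rj]) if d <= max_dist else None, d, d > max_dist))
        else:
            out.append(TargetMatch(ti, None, np.inf, True))
    return out


# ---------------------------------------------------------------------------
# Session bundle I/O
# ---------------------------------------------------------------------------
# Layout: one HDF5 file with /responses (and optional /traces) plus a
# frame_rate attribute, and companion CSV sheets <stem>.neurons.csv and
# <stem>.trials.csv next to it.  Ensembles travel in a separate JSON file.

def _companion(path: Path, sheet: str) -> Path:
    return path.with_name(path.stem + f".{sheet}.csv")


def save_session(bundle: SessionBundle, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=bundle.responses)
        if bundle.traces is not None:
            f.create_dataset("traces", data=bundle.traces)
        f.attrs["frame_rate"] = bundle.frame_rate
    # %.17g guarantees float64 round-trip through the text sheets
    bundle.neuron_frame().to_csv(_companion(path, "neurons"), index=False, float_format="%.17g")
    bundle.trial_frame().to_csv(_companion(path, "trials"), index=False, float_format="%.17g")
    return path


def load_session(path: str | Path) -> SessionBundle:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "responses" not in f:
            raise ValueError(f"{path}: missing required dataset '/responses'")
        responses = f["responses"][()]
        traces = f["traces"][()] if "traces" in f else None
        if "frame_rate" not in f.attrs:
            raise ValueError(f"{path}: missing required attribute 'frame_rate'")
        frame_rate = float(f.attrs["frame_rate"])

    neurons_path = _companion(path, "neurons")
    trials_path = _companion(path, "trials")
    for p, cols in ((neurons_path, "neurons"), (trials_path, "trials")):
        if not p.exists():
            raise ValueError(f"missing companion sheet {p} ({cols})")

    ndf = pd.read_csv(neurons_path, float_precision="round_trip")
    required = {"neuron_id", "cell_type", "x", "y", "z", "is_targeted", "plane"}
    if missing := required - set(ndf.columns):
        raise ValueError(f"{neurons_path}: missing columns {sorted(missing)}")
    neurons = [
        NeuronRecord(
            neuron_id=int(r.neuron_id),
            cell_type=str(r.cell_type),
            centroid=(float(r.x), float(r.y), float(r.z)),
            is_targeted=bool(r.is_targeted),
            plane=int(r.plane),
        )
        for r in ndf.itertuples()
    ]

    tdf = pd.read_csv(trials_path, float_precision="round_trip")
    required = {"trial_id", "vis_orientation", "stim_ensemble", "epoch", "train_block"}
    if missing := required - set(tdf.columns):
        raise ValueError(f"{trials_path}: missing columns {sorted(missing)}")
    trials = [
        TrialRecord(
            trial_id=int(r.trial_id),
            vis_orientation=None if pd.isna(r.vis_orientation) else float(r.vis_orientation),
            stim_ensemble=None if pd.isna(r.stim_ensemble) else int(r.stim_ensemble),
            epoch=str(r.epoch),
            train_block=bool(r.train_block),
        )
        for r in tdf.itertuples()
    ]
    return SessionBundle(
        responses=responses, neurons=neurons, trials=trials, traces=traces, frame_rate=frame_rate
    )


def save_ensembles(ensembles: Sequence[EnsembleSpec], path: str | Path) -> Path:
    path = Path(path)
    payload = {
        str(e.ensemble_id): {
            "member_ids": sorted(e.member_ids),
            "pref_orientation": e.pref_orientation,
            "osi": e.osi,
        }
        for e in ensembles
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def load_ensembles(path: str | Path) -> list[EnsembleSpec]:
    payload = json.loads(Path(path).read_text())
    return [
        EnsembleSpec(
            ensemble_id=int(eid),
            member_ids=frozenset(spec["member_ids"]),
            pref_orientation=float(spec["pref_orientation"]),
            osi=float(spec["osi"]),
        )
        for eid, spec in payload.items()
    ]
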