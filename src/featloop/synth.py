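"""Synthetic session generator with full ground truth.

The generator emulates the statistical structure the analyses assume:

* von Mises orientation tuning with heterogeneous selectivity — each
  neuron's mean visual response is ``A * exp(kappa*(cos(2*dtheta)-1))``
  (peak ``A`` at its preferred orientation, drawn uniformly on
  [0, 180)), with per-neuron concentration drawn from a configurable
  range so that the OSI > 0.4 filter has bite;
* additive per-trial Gaussian noise on the scalar response (sd 0.1 in
  z-units by default, matching the trial noise used in the network
  model);
* ensembles of co-tuned targeted PCs of configurable size; and
* delta-theta-dependent photostimulation effect kernels: like-to-like
  suppression/completion for PCs, size-scaled like-to-like recruitment
  for SSTs, untuned suppression for PVs.

Everything is deterministic under ``SynthConfig.seed``; per-neuron
ground truth rides along for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .data_model import EnsembleSpec, NeuronRecord, SessionBundle, TrialRecord
from .tuning import angular_difference, ensemble_tuning

# Sub-stream tags so the visual, photostim and visual+stim generators
# draw independent but seed-reproducible randomness.
_TAG_POPULATION = 1
_TAG_VISUAL = 2
_TAG_PHOTOSTIM = 3
_TAG_VISUAL_STIM = 4


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator (defaults mirror a typical
    imaging session of roughly 1,400 neurons; tests scale n down)."""

    n_pc: int = 1200
    n_sst: int = 100
    n_pv: int = 100
    kappa_tuning: tuple[float, float] = (0.5, 4.0)
    response_amplitude: float = 1.0
    noise_sd: float = 0.1
    n_trials_per_orientation: int = 20
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    target_amplitude: float = 5.0
    ensemble_amplitude_jitter: float = 0.0
    frame_rate: float = 6.0
    fov_um: tuple[float, float, float] = (500.0, 500.0, 200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pc, self.n_sst, self.n_pv) < 0:
            raise ValueError("population counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LogisticGain:
    """Monotone nondecreasing gain as a function of ensemble size."""

    slope: float = 0.5
    threshold: float = 5.0
    min: float = 0.0
    max: float = 1.0

    def __call__(self, n: float) -> float:
        return self.min + (self.max - self.min) / (1.0 + np.exp(-self.slope * (n - self.threshold)))


KERNEL_TYPES = ("like_to_like_suppression", "like_to_like_activation", "untuned_suppression")


@dataclass(frozen=True)
class EffectKernel:
    """Photostimulation effect on a non-targeted cell vs tuning offset.

    The kernel is linear in delta-theta between its anchors at 0 and 90
    degrees (the 4-orientation design only realizes offsets {0, 45, 90})
    and is multiplied by a monotone gain of ensemble size.
    """

    kernel_type: str
    amplitude_at_0: float
    amplitude_at_90: float
    size_scaling: LogisticGain | None = None

    def __post_init__(self) -> None:
        if self.kernel_type not in KERNEL_TYPES:
            raise ValueError(f"kernel_type must be one of {KERNEL_TYPES}")

    def __call__(self, delta_theta) -> np.ndarray:
        d = np.asarray(delta_theta, dtype=float)
        if np.any((d < 0) | (d > 90)):
            raise ValueError("kernel evaluates on delta_theta in [0, 90]")
        return self.amplitude_at_0 + (self.amplitude_at_90 - self.amplitude_at_0) * d / 90.0

    def gain(self, ensemble_size: int) -> float:
        return 1.0 if self.size_scaling is None else float(self.size_scaling(ensemble_size))

    def effect(self, delta_theta, ensemble_size: int) -> np.ndarray:
        return self.gain(ensemble_size) * self(delta_theta)


def sst_recruitment_kernel(
    amplitude_at_0: float = 0.6,
    amplitude_at_90: float = 0.1,
    size_scaling: LogisticGain | None = LogisticGain(slope=0.5, threshold=5.0, min=0.2, max=1.0),
) -> EffectKernel:
    """Size-scaled like-to-like SST recruitment."""
    return EffectKernel("like_to_like_activation", amplitude_at_0, amplitude_at_90, size_scaling)


def pv_suppression_kernel(amplitude: float = -0.2) -> EffectKernel:
    """Untuned PV suppression (flat in delta-theta)."""
    return EffectKernel("untuned_suppression", amplitude, amplitude)


def pc_like_to_like_suppression(
    amplitude_at_0: float = -0.3, amplitude_at_90: float = -0.05
) -> EffectKernel:
    """Co-tuned PCs suppressed more than orthogonally tuned PCs."""
    return EffectKernel("like_to_like_suppression", amplitude_at_0, amplitude_at_90)


def pc_size_dependent_kernel(
    ensemble_size: int,
    sparse: tuple[float, float] = (-0.25, 0.1),
    dense: tuple[float, float] = (0.35, -0.1),
    crossover: LogisticGain = LogisticGain(slope=1.0, threshold=5.0),
) -> EffectKernel:
    """PC effect that flips from net suppression of the co-tuned pattern
    (small ensembles) to like-to-like completion (large ensembles).

    Anchor amplitudes blend between the ``sparse`` and ``dense`` regimes
    with a logistic weight of ensemble size, reproducing the
    suppression-dominant (1-2 cells) vs completion-dominant (10-100
    cells) structure.
    """
    w = crossover(ensemble_size)
    a0 = (1 - w) * sparse[0] + w * dense[0]
    a90 = (1 - w) * sparse[1] + w * dense[1]
    kind = "like_to_like_activation" if a0 >= a90 else "like_to_like_suppression"
    return EffectKernel(kind, a0, a90)


@dataclass
class GroundTruth:
    """Per-neuron truth aligned index-for-index with the session."""

    theta_pref: np.ndarray
    kappa: np.ndarray
    amplitude: np.ndarray
    #: filled by the photostim generator: (ensemble_id, cell_type, bin) -> mean effect
    effect_means: dict = field(default_factory=dict)

    def tuning_curve(self, neuron_index: int, theta) -> np.ndarray:
        d = np.radians(2 * angular_difference(self.theta_pref[neuron_index], theta))
        return self.amplitude[neuron_index] * np.exp(self.kappa[neuron_index] * (np.cos(d) - 1.0))


def _mean_response_matrix(gt: GroundTruth, thetas) -> np.ndarray:
    """Noiseless mean response [n_neurons x len(thetas)]."""
    d = np.radians(2 * angular_difference(gt.theta_pref[:, None], np.asarray(thetas)[None, :]))
    return gt.amplitude[:, None] * np.exp(gt.kappa[:, None] * (np.cos(d) - 1.0))


def generate_population(config: SynthConfig) -> tuple[list[NeuronRecord], GroundTruth]:
    """Draw a population: uniform preferred orientations, per-neuron
    concentration from ``config.kappa_tuning``, cell types in PC/SST/PV
    blocks, centroids uniform in the imaging volume."""
    rng = np.random.default_rng([_TAG_POPULATION, config.seed])
    n = config.n_pc + config.n_sst + config.n_pv
    prefs = rng.uniform(0.0, 180.0, n)
    lo, hi = config.kappa_tuning
    kappa = rng.uniform(lo, hi, n)
    amp = np.full(n, config.response_amplitude)
    centroids = rng.uniform(0, 1, (n, 3)) * np.asarray(config.fov_um)
    types = ["PC"] * config.n_pc + ["SST"] * config.n_sst + ["PV"] * config.n_pv
    neurons = [
        NeuronRecord(
            neuron_id=i,
            cell_type=types[i],
            centroid=tuple(centroids[i]),
            is_targeted=False,
            plane=int(centroids[i, 2] // 30),
        )
        for i in range(n)
    ]
    return neurons, GroundTruth(theta_pref=prefs, kappa=kappa, amplitude=amp)


def make_cotuned_ensembles(
    neurons: Sequence[NeuronRecord],
    gt: GroundTruth,
    specs: Sequence[tuple[int, float]],
    pref_tolerance: float = 15.0,
    orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
    seed: int = 0,
) -> tuple[list[NeuronRecord], list[EnsembleSpec]]:
    """Mark co-tuned PC ensembles as targeted.

    ``specs`` is a list of ``(size, target_orientation)``.  Members are
    PCs whose true preference lies within ``pref_tolerance`` degrees of
    the target orientation, sampled without replacement across
    ensembles.  Returns the updated neuron list (targeted flags set) and
    the ensemble specs, whose preferred orientation and OSI come from
    the vector-sum tuning of the members' noiseless mean responses.
    """
    rng = np.random.default_rng([_TAG_POPULATION + 10, seed])
    available = {
        n.neuron_id
        for n in neurons
        if n.cell_type == "PC" and not n.is_targeted
    }
    ensembles = []
    flagged: set[int] = set()
    mean_R = _mean_response_matrix(gt, orientations)
    for k, (size, theta) in enumerate(specs):
        pool = [
            i for i in sorted(available)
            if angular_difference(gt.theta_pref[i], theta) <= pref_tolerance
        ]
        if len(pool) < size:
            raise ValueError(
                f"ensemble {k}: only {len(pool)} candidate PCs within "
                f"{pref_tolerance} deg of {theta} deg (need {size})"
            )
        members = rng.choice(pool, size=size, replace=False)
        available -= set(int(m) for m in members)
        flagged |= set(int(m) for m in members)
        ens_theta, ens_osi = ensemble_tuning(mean_R[members], orientations)
        ensembles.append(
            EnsembleSpec(
                ensemble_id=k,
                member_ids=frozenset(int(m) for m in members),
                pref_orientation=ens_theta,
                osi=ens_osi,
            )
        )
    updated = [
        replace(n, is_targeted=True) if n.neuron_id in flagged else n for n in neurons
    ]
    return updated, ensembles


def simulate_visual_trials(
    neurons: Sequence[NeuronRecord],
    gt: GroundTruth,
    config: SynthConfig,
    train_block: bool = False,
    trial_id_start: int = 0,
) -> SessionBundle:
    """Visual-grating session: balanced trials over the four orientations,
    response = tuning curve + Gaussian noise."""
    rng = np.random.default_rng([_TAG_VISUAL, config.seed, int(train_block)])
    n_neurons = len(neurons)
    thetas = np.repeat(config.orientations, config.n_trials_per_orientation).astype(float)
    rng.shuffle(thetas)
    mean_R = _mean_response_matrix(gt, thetas)  # [n_neurons x n_trials]
    responses = mean_R.T + rng.normal(0.0, config.noise_sd, (thetas.size, n_neurons))
    trials = [
        TrialRecord(
            trial_id=trial_id_start + i,
            vis_orientation=float(thetas[i]),
            stim_ensemble=None,
            epoch="stim_ON",
            train_block=train_block,
        )
        for i in range(thetas.size)
    ]
    return SessionBundle(
        responses=responses, neurons=list(neurons), trials=trials, frame_rate=config.frame_rate
    )


def simulate_photostim_trials(
    neurons: Sequence[NeuronRecord],
    gt: GroundTruth,
    ensembles: Sequence[EnsembleSpec],
    kernels: Mapping[str, EffectKernel | Callable[[int], EffectKernel]],
    config: SynthConfig,
    n_trials_per_ensemble: int = 10,
) -> SessionBundle:
    """Holographic-stimulation session without visual input.

    Every trial emits a paired row couple: a ``baseline_OFF`` row (pure
    noise, decoded as the control) and a ``stim_ON`` row in which
    targeted members sit at a large fixed activation and every
    non-targeted neuron receives its cell-type kernel evaluated at the
    tuning offset from the ensemble, scaled by ensemble size.  ``kernels``
    maps cell type to an :class:`EffectKernel` or to a callable
    ``size -> EffectKernel`` for size-dependent effect structure.
    """
    rng = np.random.default_rng([_TAG_PHOTOSTIM, config.seed])
    n_neurons = len(neurons)
    prefs = gt.theta_pref
    cell_types = np.array([n.cell_type for n in neurons])
    present_types = set(cell_types)
    for ct in sorted(present_types):
        if ct not in kernels:
            raise ValueError(f"no effect kernel supplied for present cell type {ct!r}")

    id_to_col = {n.neuron_id: j for j, n in enumerate(neurons)}
    rows, trials = [], []
    tid = 0
    for ens in ensembles:
        member_cols = np.array(sorted(id_to_col[m] for m in ens.member_ids))
        doff = angular_difference(ens.pref_orientation, prefs)
        mean_effect = np.zeros(n_neurons)
        for ct in sorted(present_types):
            k = kernels[ct]
            kern = k(ens.size) if callable(k) and not isinstance(k, EffectKernel) else k
            sel = cell_types == ct
            mean_effect[sel] = kern.effect(doff[sel], ens.size)
            for b in (0.0, 45.0, 90.0):
                gt.effect_means[(ens.ensemble_id, ct, b)] = float(kern.effect(b, ens.size))
        if config.ensemble_amplitude_jitter > 0:
            mean_effect = mean_effect * max(
                0.0, 1.0 + config.ensemble_amplitude_jitter * rng.standard_normal()
            )
        mean_effect[member_cols] = config.target_amplitude

        for _ in range(n_trials_per_ensemble):
            off = rng.normal(0.0, config.noise_sd, n_neurons)
            on = mean_effect + rng.normal(0.0, config.noise_sd, n_neurons)
            rows += [off, on]
            trials += [
                TrialRecord(tid, None, ens.ensemble_id, "baseline_OFF"),
                TrialRecord(tid + 1, None, ens.ensemble_id, "stim_ON"),
            ]
            tid += 2
    return SessionBundle(
        responses=np.array(rows), neurons=list(neurons), trials=trials, frame_rate=config.frame_rate
    )


def flank_suppression_kernel(amplitude: float = 0.4, width: float = 15.0):
    """Gaussian suppression of cells tuned ~45 deg off the visual stimulus."""

    def kernel(delta_theta):
        d = np.asarray(delta_theta, dtype=float)
        return -amplitude * np.exp(-0.5 * ((d - 45.0) / width) ** 2)

    return kernel


def flank_shared_suppression(
    gt: GroundTruth,
    ensemble_pref: float,
    beta: float = 0.5,
    cotuned_width: float = 22.5,
) -> Callable[[float], np.ndarray]:
    """Suppress the flank-stimulus response component of ensemble
    co-tuned cells.

    On a trial with visual orientation theta, every cell whose true
    preference lies within ``cotuned_width`` of the ensemble preference
    loses ``beta`` times its mean tuning-curve response to the two
    flanking orientations (theta +/- 45); all other cells are
    untouched.  Use as ``trial_effect`` in
    :func:`simulate_visual_photostim_trials`.
    """

    def trial_effect(vis_theta: float) -> np.ndarray:
        co = angular_difference(gt.theta_pref, ensemble_pref) < cotuned_width
        flank = 0.5 * (
            _mean_response_matrix(gt, [vis_theta + 45.0])[:, 0]
            + _mean_response_matrix(gt, [vis_theta - 45.0])[:, 0]
        )
        return np.where(co, -beta * flank, 0.0)

    return trial_effect


def simulate_visual_photostim_trials(
    neurons: Sequence[NeuronRecord],
    gt: GroundTruth,
    ensemble: EnsembleSpec,
    config: SynthConfig,
    cell_effect: Callable[[np.ndarray], np.ndarray] | None = None,
    trial_effect: Callable[[float], np.ndarray] | None = None,
    reference: str = "vis",
    gate: str = "aligned",
    n_train_per_orientation: int = 20,
    n_test_per_orientation: int = 20,
) -> SessionBundle:
    """Visual stimulation with interleaved ensemble photostimulation.

    Emits an independent visual-only training block (``train_block``
    True) followed by interleaved test trials: for each orientation,
    ``n_test_per_orientation`` stim-OFF trials (no photostim) and the
    same number of stim-ON trials.  On ON trials, targeted members are
    driven to the target amplitude and non-targeted cells receive
    ``cell_effect(delta_theta)`` where the offset is measured from the
    visual stimulus (``reference="vis"``) or the ensemble preference
    (``reference="ensemble"``).  With ``gate="aligned"`` the effect only
    applies on trials where the visual stimulus is aligned with the
    ensemble (offset < 45 deg); ``gate="all"`` applies it on every ON
    trial.  ``trial_effect`` (exclusive with ``cell_effect``) instead
    supplies the full per-neuron effect vector as a function of the
    visual orientation, for structured effects such as
    :func:`flank_shared_suppression`.
    """
    if (cell_effect is None) == (trial_effect is None):
        raise ValueError("provide exactly one of cell_effect or trial_effect")
    if reference not in ("vis", "ensemble"):
        raise ValueError("reference must be 'vis' or 'ensemble'")
    if gate not in ("aligned", "all"):
        raise ValueError("gate must be 'aligned' or 'all'")
    rng = np.random.default_rng([_TAG_VISUAL_STIM, config.seed])
    n_neurons = len(neurons)
    id_to_col = {n.neuron_id: j for j, n in enumerate(neurons)}
    member_cols = np.array(sorted(id_to_col[m] for m in ensemble.member_ids))

    rows, trials = [], []
    tid = 0
    # independent visual-only training block
    train_thetas = np.repeat(config.orientations, n_train_per_orientation).astype(float)
    rng.shuffle(train_thetas)
    for th in train_thetas:
        base = _mean_response_matrix(gt, [th])[:, 0]
        rows.append(base + rng.normal(0, config.noise_sd, n_neurons))
        trials.append(TrialRecord(tid, float(th), None, "stim_ON", train_block=True))
        tid += 1
    # interleaved test block
    test = []
    for th in config.orientations:
        test += [(float(th), False)] * n_test_per_orientation
        test += [(float(th), True)] * n_test_per_orientation
    order = rng.permutation(len(test))
    for k in order:
        th, stim_on = test[k]
        resp = _mean_response_matrix(gt, [th])[:, 0] + rng.normal(0, config.noise_sd, n_neurons)
        if stim_on:
            aligned = angular_difference(th, ensemble.pref_orientation) < 45.0
            if gate == "all" or aligned:
                if trial_effect is not None:
                    resp = resp + trial_effect(th)
                else:
                    ref = th if reference == "vis" else ensemble.pref_orientation
                    resp = resp + cell_effect(angular_difference(ref, gt.theta_pref))
            resp[member_cols] = config.target_amplitude
        trials.append(
            TrialRecord(tid, th, ensemble.ensemble_id if stim_on else None, "stim_ON")
        )
        rows.append(resp)
        tid += 1
    return SessionBundle(
        responses=np.array(rows), neurons=list(neurons), trials=trials, frame_rate=config.frame_rate
    )
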