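"""Synthetic slice models: thresholded neurons read out as summed ΔF/F.

The generative model mirrors a multi-electrode slice-stimulation
experiment.  Each *cell group* (the unit imaged as one ROI) holds a
small number of neurons.  Neuron ``j`` receives a lumped drive
``I·w_j`` from the binary stimulation pattern ``I`` through its
per-electrode weight vector ``w_j``, passes it through a
dendrite-to-soma transform ``f``, and fires a single all-or-none
calcium event iff the drive exceeds its spike threshold ``T_j``:

    r_j = 1  iff  f(I·w_j) - inhibition > T_j,   else 0

The group's recorded peak ΔF/F is the sum of the unit fluorescence
amplitudes of the neurons that fired, plus trial noise:

    O = sum_j (ΔF/F)_j * r_j + noise,   clipped below at 0.

Tonic inhibition is subtractive on the drive (a constant offset
current); blocking inhibition (picrotoxin) sets the offset to zero.
Reduced stimulation current scales the drive by a factor ``a`` before
the transform; LTP multiplies the weights on the tetanized electrode
and, with homeostasis, all spike thresholds.

Neurons with ``threshold == 0`` are treated as *graded* linear units
contributing ``amplitude * max(drive, 0)``: the threshold-free limit
used for exact gain/offset identifiability checks, not part of the
default generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import StimulusPattern, enumerate_patterns
from .response import COLUMNS, ResponseMatrix

TransformKind = Literal["identity", "saturating", "expansive"]


def _apply_transform(x: np.ndarray | float, kind: TransformKind, param: float) -> np.ndarray | float:
    """Dendrite-to-soma transform f, monotone with f(0)=0 on x >= 0."""
    if kind == "identity":
        return x
    if kind == "saturating":
        # soft saturation at `param` drive units
        return param * np.tanh(np.asarray(x, dtype=float) / param)
    if kind == "expansive":
        return np.power(np.asarray(x, dtype=float), param)
    raise ValueError(f"unknown transform kind {kind!r}")


@dataclass(frozen=True)
class NeuronModel:
    """One thresholded neuron with lumped per-electrode weights."""

    weights: tuple[float, ...]
    threshold: float
    amplitude: float
    transform_kind: TransformKind = "identity"
    transform_param: float = 1.0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    def drive(self, pattern_vec: np.ndarray, scale: float = 1.0, inhibition: float = 0.0) -> float:
        raw = float(pattern_vec @ np.asarray(self.weights))
        return float(_apply_transform(scale * raw, self.transform_kind, self.transform_param)) - inhibition

    def response(self, pattern_vec: np.ndarray, scale: float = 1.0, inhibition: float = 0.0) -> float:
        d = self.drive(pattern_vec, scale, inhibition)
        if self.threshold == 0.0:
            return self.amplitude * max(d, 0.0)  # graded linear limit
        return self.amplitude if d > self.threshold else 0.0


@dataclass(frozen=True)
class CellGroupModel:
    """A small set of neurons imaged together as one ROI."""

    group_id: str
    neurons: tuple[NeuronModel, ...]

    def __post_init__(self) -> None:
        if len(self.neurons) < 1:
            raise ValueError("cell group needs at least one neuron")

    @property
    def size(self) -> int:
        return len(self.neurons)

    @property
    def total_amplitude(self) -> float:
        return sum(n.amplitude for n in self.neurons)

    def output(self, pattern_vec: np.ndarray, scale: float = 1.0, inhibition: float = 0.0) -> float:
        return sum(n.response(pattern_vec, scale, inhibition) for n in self.neurons)


@dataclass(frozen=True)
class SliceModel:
    """A simulated slice: electrode array, cell groups, noise model."""

    n_electrodes: int
    groups: tuple[CellGroupModel, ...]
    inhibition_offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("need at least one electrode")
        if self.inhibition_offset < 0:
            raise ValueError("inhibition_offset must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for g in self.groups:
            for n in g.neurons:
                if len(n.weights) != self.n_electrodes:
                    raise ValueError(
                        f"group {g.group_id}: weight vector length {len(n.weights)} "
                        f"!= n_electrodes {self.n_electrodes}"
                    )


@dataclass(frozen=True)
class PerturbationSpec:
    """A network perturbation applied before thresholding.

    kinds
    -----
    ``scale_input``
        Multiply every neuron's raw drive ``I·w`` by ``scale_a``
        (reduced stimulation current; the reference protocol uses 0.75).
    ``block_inhibition``
        Set the subtractive inhibition offset to zero (picrotoxin).
    ``ltp``
        Multiply weights on ``ltp_electrode`` by ``ltp_factor`` and,
        modelling homeostasis, all spike thresholds by
        ``homeostatic_threshold_factor``.
    """

    kind: Literal["scale_input", "block_inhibition", "ltp"]
    scale_a: float = 0.75
    ltp_electrode: int = 0
    ltp_factor: float = 1.5
    homeostatic_threshold_factor: float = 1.05

    def __post_init__(self) -> None:
        if self.kind == "scale_input" and not 0 < self.scale_a <= 1:
            raise ValueError("scale_a must lie in (0, 1]")
        if self.ltp_factor < 1:
            raise ValueError("ltp_factor must be >= 1")
        if self.homeostatic_threshold_factor < 1:
            raise ValueError("homeostatic_threshold_factor must be >= 1")


def apply_perturbation(slc: SliceModel, perturbation: Optional[PerturbationSpec]) -> tuple[SliceModel, float]:
    """Return the effective (slice, drive scale) pair under a perturbation."""
    if perturbation is None:
        return slc, 1.0
    if perturbation.kind == "scale_input":
        return slc, perturbation.scale_a
    if perturbation.kind == "block_inhibition":
        return replace(slc, inhibition_offset=0.0), 1.0
    if perturbation.kind == "ltp":
        if not 0 <= perturbation.ltp_electrode < slc.n_electrodes:
            raise ValueError(f"ltp_electrode {perturbation.ltp_electrode} out of range")
        new_groups = []
        for g in slc.groups:
            new_neurons = []
            for n in g.neurons:
                w = list(n.weights)
                w[perturbation.ltp_electrode] *= perturbation.ltp_factor
                new_neurons.append(
                    replace(
                        n,
                        weights=tuple(w),
                        threshold=n.threshold * perturbation.homeostatic_threshold_factor,
                    )
                )
            new_groups.append(replace(g, neurons=tuple(new_neurons)))
        return replace(slc, groups=tuple(new_groups)), 1.0
    raise ValueError(f"unknown perturbation kind {perturbation.kind!r}")


# ---------------------------------------------------------------------------
# Generator configuration and construction
# ---------------------------------------------------------------------------

# Group sizes follow a truncated geometric distribution on {2..10},
# P(k) ∝ GROUP_SIZE_DECAY**(k-2), with the decay chosen so the mean is 4
# (matching the ~4 overlapping neurons estimated per ROI).
GROUP_SIZE_SUPPORT = np.arange(2, 11)
GROUP_SIZE_DECAY = 0.70734


def group_size_probabilities() -> np.ndarray:
    p = GROUP_SIZE_DECAY ** (GROUP_SIZE_SUPPORT - 2)
    return p / p.sum()


@dataclass(frozen=True)
class SliceConfig:
    """Generator settings for :func:`build_slice`.

    Defaults emulate the reference preparation: a five-electrode array,
    15 cell groups per slice, 2-10 neurons per group averaging 4,
    heterogeneous lognormal weights, normal spike thresholds truncated
    at zero, lognormal unit ΔF/F amplitudes, a tonic subtractive
    inhibition offset, and Gaussian trial noise on the peak ΔF/F.
    """

    n_electrodes: int = 5
    n_groups: int = 15
    rho: float = 0.0                      # within-group weight correlation (log scale)
    weight_median: float = 0.7            # lognormal median, drive units per electrode
    weight_sigma: float = 1.0             # lognormal shape (log-SD): "wide range" of weights
    threshold_mean: float = 2.0           # drive units
    threshold_sd: float = 0.3
    amplitude_median: float = 0.03        # unit ΔF/F per neuron
    amplitude_sigma: float = 0.3
    inhibition_offset: float = 0.15       # tonic subtractive offset, drive units
    noise_sd: float = 0.01                # trial noise SD on peak ΔF/F
    transform_kind: TransformKind = "identity"
    transform_param: float = 1.0
    group_size_low: int = 2
    group_size_high: int = 10
    fixed_group_size: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")


def _draw_group_sizes(cfg: SliceConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.fixed_group_size is not None:
        return np.full(cfg.n_groups, cfg.fixed_group_size, dtype=int)
    if (cfg.group_size_low, cfg.group_size_high) == (2, 10):
        return rng.choice(GROUP_SIZE_SUPPORT, size=cfg.n_groups, p=group_size_probabilities())
    return rng.integers(cfg.group_size_low, cfg.group_size_high + 1, size=cfg.n_groups)


def build_slice(config: SliceConfig) -> SliceModel:
    """Draw a reproducible synthetic slice from a generator config.

    Weight heterogeneity is controlled by ``rho``: log-weights are a
    mixture ``sqrt(rho) * g + sqrt(1 - rho) * z`` of a per-(group,
    electrode) factor ``g`` and an independent per-neuron factor ``z``,
    so ``rho = 0`` draws fully independent weight vectors per neuron and
    ``rho = 1`` gives every neuron in a group the same weights.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    sizes = _draw_group_sizes(cfg, rng)

    groups = []
    mu_w = math.log(cfg.weight_median)
    for gi, size in enumerate(sizes):
        shared = rng.standard_normal(cfg.n_electrodes)
        neurons = []
        log_amp = rng.normal(math.log(cfg.amplitude_median), cfg.amplitude_sigma, size=size)
        thr = stats.truncnorm.rvs(
            a=-cfg.threshold_mean / cfg.threshold_sd,
            b=np.inf,
            loc=cfg.threshold_mean,
            scale=cfg.threshold_sd,
            size=size,
            random_state=rng,
        )
        for ni in range(size):
            own = rng.standard_normal(cfg.n_electrodes)
            z = math.sqrt(cfg.rho) * shared + math.sqrt(1.0 - cfg.rho) * own
            w = np.exp(mu_w + cfg.weight_sigma * z)
            neurons.append(
                NeuronModel(
                    weights=tuple(float(x) for x in w),
                    threshold=float(thr[ni]),
                    amplitude=float(np.exp(log_amp[ni])),
                    transform_kind=cfg.transform_kind,
                    transform_param=cfg.transform_param,
                )
            )
        groups.append(CellGroupModel(group_id=f"g{gi:03d}", neurons=tuple(neurons)))

    return SliceModel(
        n_electrodes=cfg.n_electrodes,
        groups=tuple(groups),
        inhibition_offset=cfg.inhibition_offset,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_response(
    slc: SliceModel,
    pattern: StimulusPattern,
    perturbation: Optional[PerturbationSpec] = None,
    trial_seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Peak ΔF/F of every group for one pattern and one trial.

    ``trial_seed`` may be an integer seed, a Generator (consumed), or
    None for a noise-free evaluation regardless of the slice noise SD.
    """
    if pattern.n_electrodes != slc.n_electrodes:
        raise ValueError(
            f"pattern has {pattern.n_electrodes} electrodes, slice has {slc.n_electrodes}"
        )
    eff, scale = apply_perturbation(slc, perturbation)
    vec = pattern.as_array()
    clean = np.array([g.output(vec, scale, eff.inhibition_offset) for g in eff.groups])
    if trial_seed is None or slc.noise_sd == 0:
        return clean
    rng = (
        trial_seed
        if isinstance(trial_seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(trial_seed))
    )
    noisy = clean + rng.normal(0.0, slc.noise_sd, size=clean.shape)
    return np.clip(noisy, 0.0, None)


def run_experiment(
    slc: SliceModel,
    perturbation: Optional[PerturbationSpec] = None,
    trials: int = 3,
    seed: int = 0,
) -> ResponseMatrix:
    """Record all ``2**N_EL - 1`` patterns x trials for every group.

    Each input pattern is repeated ``trials`` times (three in the
    reference protocol); noise is drawn independently per (group,
    pattern, trial) from a generator seeded by ``seed``, so a fixed
    (slice, perturbation, seed) triple reproduces the matrix exactly.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    for pat in enumerate_patterns(slc.n_electrodes):
        for trial in range(trials):
            vals = simulate_response(slc, pat, perturbation, trial_seed=rng)
            for g, v in zip(slc.groups, vals):
                records.append(
                    {
                        "group_id": g.group_id,
                        "pattern_id": pat.pattern_id,
                        "pattern_bits": pat.bits_string,
                        "trial": trial,
                        "peak_dff": float(v),
                    }
                )
    return ResponseMatrix(
        data=pd.DataFrame.from_records(records, columns=COLUMNS),
        n_electrodes=slc.n_electrodes,
    )


def effective_weights(group: CellGroupModel) -> np.ndarray:
    """Amplitude-weighted sum of graded-neuron weights.

    For a threshold-free (graded, identity-transform) group the output
    is exactly ``pattern @ effective_weights``, which is the ground
    truth that a least-squares weight fit should recover.
    """
    return np.sum(
        [np.asarray(n.weights) * n.amplitude for n in group.neurons], axis=0
    )
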