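"""Synthetic cohorts of coupled resting-state network time-courses.

No scan data ship with this package, so every downstream stage is
exercised on synthetic cohorts with the statistical structure the
analysis assumes.  The generative model is a *latent-driver* model: each
edge of a coupling graph owns a band-limited (0.01-0.1 Hz) latent
signal that is injected into both endpoint nodes — into the second
endpoint at the edge's lag and through the edge's (optionally nonlinear)
transform, with amplitude proportional to the edge weight.  Independent
band-limited noise is added per node and columns are standardized.  This
gives direct control over exactly the properties the lagged distance
correlation must detect: per-edge coupling strength, small temporal
lags, and nonlinearity.

Cohorts emulate three populations — healthy controls (HC) and patients
in minimally conscious state (MCS) or unresponsive wakefulness syndrome
(UWS) — by degrading a shared base graph per group: independent edge
deletion, weight attenuation, and noise inflation, graded with clinical
severity.  Defaults follow the acquisition actually analysed: 10
networks, 297 retained volumes at a 2 s sampling interval, and group
sizes 27/24/24.

Also provided: synthetic spatial components for template-matching
benchmarks, the three artifactual time-course signatures (high-frequency,
spike, sawtooth), and rigid-body motion traces for motion QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .exceptions import InvalidArgumentError
from .rsn import SpatialComponentSet, TemplateSet
from .timecourses import MIN_TIMEPOINTS, RSN_LABELS, TimeCourseSet

__all__ = [
    "CouplingGraph",
    "GroupDegradation",
    "CohortSpec",
    "NEURONAL_BAND_HZ",
    "bandlimited_noise",
    "generate_coupling_graph",
    "simulate_timecourses",
    "generate_cohort",
    "generate_spatial_components",
    "generate_artifact_timecourse",
    "generate_neuronal_timecourse",
    "generate_motion_trace",
]

#: Frequency band (Hz) of neuronal resting-state fluctuations; artifact
#: screening treats power above its upper edge as suspicious.
NEURONAL_BAND_HZ: tuple[float, float] = (0.01, 0.1)

NONLINEARITIES = ("linear", "quadratic", "monotone")


@dataclass
class CouplingGraph:
    """Ground-truth interaction structure between networks.

    ``weights`` is symmetric with zero diagonal; ``lags[i, j]`` (samples,
    antisymmetric) is the delay of node j's copy of the shared driver
    relative to node i's; ``nonlinearity`` maps an edge ``(i, j)`` with
    ``i < j`` to the transform applied to the driver before injection
    into j.
    """

    node_labels: list[str]
    weights: np.ndarray
    lags: np.ndarray
    nonlinearity: dict[tuple[int, int], str] = field(default_factory=dict)
    max_structural_lag: int = 3

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.lags = np.asarray(self.lags, dtype=int)
        n = len(self.node_labels)
        if self.weights.shape != (n, n) or self.lags.shape != (n, n):
            raise InvalidArgumentError("weights and lags must be n x n")
        if not np.allclose(self.weights, self.weights.T):
            raise InvalidArgumentError("weights must be symmetric")
        if np.any(np.diagonal(self.weights) != 0):
            raise InvalidArgumentError("weight diagonal must be exactly zero")
        if np.any(self.weights < 0):
            raise InvalidArgumentError("weights must be nonnegative")
        if np.any(self.lags != -self.lags.T):
            raise InvalidArgumentError("lags must be antisymmetric")
        if np.abs(self.lags).max(initial=0) > self.max_structural_lag:
            raise InvalidArgumentError("a lag exceeds max_structural_lag")
        for (i, j), tag in self.nonlinearity.items():
            if not (0 <= i < j < n):
                raise InvalidArgumentError(f"bad edge key ({i}, {j})")
            if tag not in NONLINEARITIES:
                raise InvalidArgumentError(f"unknown nonlinearity {tag!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def edges(self):
        """Yield (i, j, weight, lag, nonlinearity) for every positive edge."""
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                w = self.weights[i, j]
                if w > 0:
                    yield i, j, w, int(self.lags[i, j]), self.nonlinearity.get(
                        (i, j), "linear"
                    )


@dataclass(frozen=True)
class GroupDegradation:
    """Per-group degradation of the base coupling graph.

    Each edge is deleted independently with ``edge_deletion_prob``;
    surviving weights are multiplied by ``1 - weight_attenuation``; node
    noise is scaled by ``noise_inflation``.  The identity degradation is
    ``(0, 0, 1)``.
    """

    edge_deletion_prob: float = 0.0
    weight_attenuation: float = 0.0
    noise_inflation: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.edge_deletion_prob <= 1:
            raise InvalidArgumentError("edge_deletion_prob must be in [0, 1]")
        if not 0 <= self.weight_attenuation <= 1:
            raise InvalidArgumentError("weight_attenuation must be in [0, 1]")
        if self.noise_inflation < 1:
            raise InvalidArgumentError("noise_inflation must be >= 1")


def _default_degradation() -> dict[str, GroupDegradation]:
    """Study conditions for the three populations: HC keep the base graph;
    MCS and UWS lose and attenuate coupling with graded severity."""
    return {
        "HC": GroupDegradation(0.0, 0.0, 1.0),
        "MCS": GroupDegradation(0.25, 0.25, 1.25),
        "UWS": GroupDegradation(0.5, 0.5, 1.5),
    }


@dataclass
class CohortSpec:
    """Full description of a synthetic three-group cohort."""

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"HC": 27, "MCS": 24, "UWS": 24}
    )
    n_timepoints: int = 297
    sampling_interval: float = 2.0
    base_graph: CouplingGraph | None = None
    degradation: dict[str, GroupDegradation] = field(
        default_factory=_default_degradation
    )
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < MIN_TIMEPOINTS:
            raise InvalidArgumentError(f"n_timepoints must be >= {MIN_TIMEPOINTS}")
        for g, n in self.n_subjects.items():
            if n < 1:
                raise InvalidArgumentError(f"group {g!r} must have >= 1 subject")
            if g not in self.degradation:
                raise InvalidArgumentError(f"no degradation given for group {g!r}")


def bandlimited_noise(
    n_timepoints: int,
    sampling_interval: float,
    rng: np.random.Generator,
    band: tuple[float, float] = NEURONAL_BAND_HZ,
) -> np.ndarray:
    """Gaussian noise band-passed to ``band`` (Hz), standardized.

    White noise is transformed to the frequency domain, components
    outside the band are zeroed, and the result is standardized to zero
    mean, unit variance.  Falls back to the nearest nonzero frequency bin
    when the series is too short to contain the band.
    """
    if n_timepoints < 4:
        raise InvalidArgumentError("need at least 4 samples")
    spectrum = np.fft.rfft(rng.standard_normal(n_timepoints))
    freqs = np.fft.rfftfreq(n_timepoints, d=sampling_interval)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        keep[min(1, keep.size - 1)] = True
    spectrum[~keep] = 0.0
    x = np.fft.irfft(spectrum, n=n_timepoints)
    sd = x.std()
    if sd == 0:  # pragma: no cover - requires pathological rng output
        raise InvalidArgumentError("degenerate band-limited draw")
    return (x - x.mean()) / sd


def generate_coupling_graph(
    n_nodes: int,
    density: float,
    weight_range: tuple[float, float],
    max_lag: int,
    seed: int,
    node_labels: list[str] | None = None,
    nonlinearity_choices: tuple[str, ...] = ("linear",),
) -> CouplingGraph:
    """Random symmetric coupling graph.

    Each of the ``n (n - 1) / 2`` node pairs receives an edge
    independently with probability ``density``; edge weights are uniform
    on ``weight_range`` (a subset of (0, 1]), lags uniform on integer
    ``[-max_lag, max_lag]``, and nonlinearity tags drawn uniformly from
    ``nonlinearity_choices``.  Deterministic in ``seed``.
    """
    if n_nodes < 2:
        raise InvalidArgumentError("n_nodes must be >= 2")
    if not 0 < density <= 1:
        raise InvalidArgumentError("density must be in (0, 1]")
    lo, hi = weight_range
    if not (0 < lo <= hi <= 1):
        raise InvalidArgumentError("weight_range must lie within (0, 1]")
    if max_lag < 0:
        raise InvalidArgumentError("max_lag must be >= 0")
    for tag in nonlinearity_choices:
        if tag not in NONLINEARITIES:
            raise InvalidArgumentError(f"unknown nonlinearity {tag!r}")
    if node_labels is None:
        node_labels = (
            list(RSN_LABELS)
            if n_nodes == len(RSN_LABELS)
            else [f"node-{k:02d}" for k in range(n_nodes)]
        )
    if len(node_labels) != n_nodes:
        raise InvalidArgumentError("need one label per node")
    rng = np.random.default_rng(seed)
    weights = np.zeros((n_nodes, n_nodes))
    lags = np.zeros((n_nodes, n_nodes), dtype=int)
    nonlinearity: dict[tuple[int, int], str] = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < density:
                w = rng.uniform(lo, hi)
                lag = int(rng.integers(-max_lag, max_lag + 1))
                weights[i, j] = weights[j, i] = w
                lags[i, j] = lag
                lags[j, i] = -lag
                nonlinearity[(i, j)] = str(rng.choice(nonlinearity_choices))
    return CouplingGraph(
        node_labels=list(node_labels),
        weights=weights,
        lags=lags,
        nonlinearity=nonlinearity,
        max_structural_lag=max(max_lag, int(np.abs(lags).max(initial=0))),
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise InvalidArgumentError(
            "constant column: increase noise_sd or add coupling"
        )
    return (x - x.mean()) / sd


def _transform_driver(driver: np.ndarray, tag: str) -> np.ndarray:
    """Edge nonlinearity applied to the shared driver before injection."""
    if tag == "linear":
        return driver
    if tag == "quadratic":
        return _standardize(driver**2)
    if tag == "monotone":  # rank-preserving odd cubic
        return _standardize(driver**3)
    raise InvalidArgumentError(f"unknown nonlinearity {tag!r}")


def simulate_timecourses(
    graph: CouplingGraph,
    n_timepoints: int = 297,
    sampling_interval: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    meta: dict | None = None,
) -> TimeCourseSet:
    """Simulate one subject's network time-courses from a coupling graph.

    Each edge's latent driver is injected into endpoint i directly and
    into endpoint j after a circular shift by the edge lag and the edge
    nonlinearity, both with amplitude equal to the edge weight.
    Band-limited node noise of standard deviation ``noise_sd`` is added
    and every column is standardized, so only *relative* driver-to-noise
    amplitude matters.  Deterministic in ``seed``.
    """
    if n_timepoints < MIN_TIMEPOINTS:
        raise InvalidArgumentError(f"n_timepoints must be >= {MIN_TIMEPOINTS}")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    data = np.zeros((n_timepoints, n))
    for node in range(n):
        if noise_sd > 0:
            data[:, node] = noise_sd * bandlimited_noise(
                n_timepoints, sampling_interval, rng
            )
    for i, j, w, lag, tag in graph.edges():
        driver = bandlimited_noise(n_timepoints, sampling_interval, rng)
        data[:, i] += w * driver
        data[:, j] += w * np.roll(_transform_driver(driver, tag), lag)
    data = np.apply_along_axis(_standardize, 0, data)
    return TimeCourseSet(
        data=data,
        labels=list(graph.node_labels),
        sampling_interval=sampling_interval,
        neuronal=np.ones(n, dtype=bool),
        meta={"seed": seed, **(meta or {})},
    )


def _subject_seeds(spec_seed: int, group_index: int, subject_index: int):
    """Two independent sub-seeds (degradation draw, simulation) per subject,
    each below 2**31, derived deterministically from the cohort seed."""
    ss = np.random.SeedSequence(
        entropy=spec_seed, spawn_key=(group_index, subject_index)
    )
    a, b = ss.generate_state(2)
    return int(a % (2**31)), int(b % (2**31))


def _degrade_graph(
    graph: CouplingGraph, deg: GroupDegradation, rng: np.random.Generator
) -> CouplingGraph:
    weights = graph.weights.copy()
    for i in range(graph.n_nodes):
        for j in range(i + 1, graph.n_nodes):
            if weights[i, j] == 0:
                continue
            if rng.random() < deg.edge_deletion_prob:
                weights[i, j] = weights[j, i] = 0.0
            else:
                weights[i, j] = weights[j, i] = weights[i, j] * (
                    1 - deg.weight_attenuation
                )
    return CouplingGraph(
        node_labels=list(graph.node_labels),
        weights=weights,
        lags=graph.lags.copy(),
        nonlinearity=dict(graph.nonlinearity),
        max_structural_lag=graph.max_structural_lag,
    )


def default_base_graph(seed: int = 0) -> CouplingGraph:
    """Default healthy-control interaction structure: 10 networks, 40 %
    edge density, moderate-to-strong weights, lags up to 3 samples, and a
    minority of nonlinear edges."""
    return generate_coupling_graph(
        n_nodes=10,
        density=0.4,
        weight_range=(0.5, 0.9),
        max_lag=3,
        seed=seed,
        nonlinearity_choices=("linear", "linear", "quadratic", "monotone"),
    )


def generate_cohort(spec: CohortSpec) -> dict[str, list[TimeCourseSet]]:
    """Simulate every subject of a three-group cohort.

    Group ``g`` uses the base graph with each edge independently deleted
    with probability ``edge_deletion_prob(g)``, surviving weights scaled
    by ``1 - weight_attenuation(g)``, and node noise scaled by
    ``noise_inflation(g)``.  Subject-level seeds derive deterministically
    from ``spec.seed`` so any subject can be regenerated independently.
    """
    base = spec.base_graph if spec.base_graph is not None else default_base_graph()
    cohort: dict[str, list[TimeCourseSet]] = {}
    for g_idx, (group, n_subj) in enumerate(sorted(spec.n_subjects.items())):
        deg = spec.degradation[group]
        subjects = []
        for s_idx in range(n_subj):
            seed_deg, seed_sim = _subject_seeds(spec.seed, g_idx, s_idx)
            graph_s = _degrade_graph(base, deg, np.random.default_rng(seed_deg))
            subjects.append(
                simulate_timecourses(
                    graph_s,
                    n_timepoints=spec.n_timepoints,
                    sampling_interval=spec.sampling_interval,
                    noise_sd=spec.noise_sd * deg.noise_inflation,
                    seed=seed_sim,
                    meta={"group": group, "subject": f"{group}-{s_idx:03d}"},
                )
            )
        cohort[group] = subjects
    return cohort


def generate_spatial_components(
    templates: TemplateSet,
    jitter: int = 1,
    noise_sd: float = 0.1,
    n_extra: int = 20,
    seed: int = 0,
) -> SpatialComponentSet:
    """Noisy, jittered copies of each template plus unrelated blob components.

    Each template mask is smoothed into an amplitude map, shifted by an
    integer offset drawn uniformly from ``[-jitter, jitter]`` per axis,
    and degraded with Gaussian voxel noise; ``n_extra`` additional
    components are random Gaussian blobs.  Component order is shuffled.
    ``source`` records the generating template per component ("extra" for
    blobs) as ground truth for benchmarks.
    """
    grid = templates.grid
    if jitter < 0 or jitter >= min(grid):
        raise InvalidArgumentError("jitter must be >= 0 and smaller than the grid")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    if n_extra < 0:
        raise InvalidArgumentError("n_extra must be >= 0")
    rng = np.random.default_rng(seed)
    maps, sources = [], []
    for name, mask in zip(templates.names, templates.masks):
        amp = mask.astype(float)
        if jitter > 0 or noise_sd > 0:
            amp = ndimage.gaussian_filter(amp, sigma=1.0)
            amp /= amp.max()
        shift = rng.integers(-jitter, jitter + 1, size=len(grid)) if jitter else None
        if shift is not None:
            amp = np.roll(amp, shift, axis=tuple(range(len(grid))))
        amp = amp + noise_sd * rng.standard_normal(grid)
        maps.append(amp)
        sources.append(name)
    coords = np.indices(grid)
    for k in range(n_extra):
        center = [rng.uniform(0.15, 0.85) * g for g in grid]
        sigma = rng.uniform(0.04, 0.10) * min(grid)
        d2 = sum((coords[a] - center[a]) ** 2 for a in range(len(grid)))
        blob = np.exp(-d2 / (2 * sigma**2))
        maps.append(blob + noise_sd * rng.standard_normal(grid))
        sources.append("extra")
    order = rng.permutation(len(maps))
    return SpatialComponentSet(
        maps=np.stack([maps[k] for k in order]),
        ids=[f"IC{k + 1:02d}" for k in range(len(maps))],
        source=[sources[k] for k in order],
    )


def generate_artifact_timecourse(
    kind: str,
    n_timepoints: int = 297,
    sampling_interval: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """One artifactual time-course signature, standardized.

    ``"highfreq"`` concentrates spectral power above 0.1 Hz;
    ``"spike"`` superposes 1-3 abrupt excursions (> 5 baseline SD) on low
    noise; ``"sawtooth"`` is a periodic ramp with mild noise.
    """
    if n_timepoints < MIN_TIMEPOINTS:
        raise InvalidArgumentError(f"n_timepoints must be >= {MIN_TIMEPOINTS}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints) * sampling_interval
    nyquist = 0.5 / sampling_interval
    if kind == "highfreq":
        upper = max(nyquist, 0.1 * 1.5)
        x = bandlimited_noise(
            n_timepoints, sampling_interval, rng, band=(0.1 + 1e-9, upper)
        )
    elif kind == "spike":
        x = 0.3 * rng.standard_normal(n_timepoints)
        n_spikes = int(rng.integers(1, 4))
        pos = rng.choice(n_timepoints, size=n_spikes, replace=False)
        x[pos] += rng.choice([-6.0, 6.0], size=n_spikes)
    elif kind == "sawtooth":
        period_s = 20 * sampling_interval
        x = signal.sawtooth(2 * np.pi * t / period_s)
        x = x + 0.05 * rng.standard_normal(n_timepoints)
    else:
        raise InvalidArgumentError(f"unknown artifact kind {kind!r}")
    return _standardize(x)


def generate_neuronal_timecourse(
    n_timepoints: int = 297, sampling_interval: float = 2.0, seed: int = 0
) -> np.ndarray:
    """A neuronal-like time-course: band-limited 0.01-0.1 Hz noise."""
    return bandlimited_noise(
        n_timepoints, sampling_interval, np.random.default_rng(seed)
    )


def generate_motion_trace(
    n_frames: int,
    base_sd_mm: float = 0.01,
    spike_frames: tuple[int, ...] = (),
    spike_size_mm: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Rigid-body motion trace: random-walk drift plus step displacements.

    Columns are 3 translations (mm) and 3 rotations (radians); rotation
    increments are scaled so their arc-length contribution matches the
    translational one.  Each frame in ``spike_frames`` gets a persistent
    ``spike_size_mm`` step in x, producing a single frame-wise
    displacement excursion there.
    """
    if n_frames < 2:
        raise InvalidArgumentError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    increments = np.empty((n_frames, 6))
    increments[:, :3] = base_sd_mm * rng.standard_normal((n_frames, 3))
    increments[:, 3:] = (base_sd_mm / 50.0) * rng.standard_normal((n_frames, 3))
    increments[0] = 0.0
    trace = np.cumsum(increments, axis=0)
    for f in spike_frames:
        if not 1 <= f < n_frames:
            raise InvalidArgumentError(f"spike frame {f} out of range")
        trace[f:, 0] += spike_size_mm
    return trace
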