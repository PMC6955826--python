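"""Resting-state network identification from independent components.

Spatial ICA of resting fMRI yields ~30 spatial maps with associated
time-courses.  Two steps recover the 10 canonical RSNs among them:

1. **Template matching** — each RSN template (a binary mask) must claim
   exactly one component and no component may be claimed twice.  The
   goodness-of-fit of a component to a template is the mean absolute
   amplitude inside the mask minus the mean outside; the assignment
   maximizing total goodness-of-fit is found by optimal linear
   assignment on the template x component score matrix.
2. **Neuronal/artifactual labeling** — every component is summarized by
   an 11-feature spatio-temporal fingerprint (degree of clustering,
   skewness, kurtosis, spatial entropy; one-lag autocorrelation,
   temporal entropy, and the power fractions of five frequency bands up
   to 0.25 Hz) and classified by a linear maximum-margin classifier.
   Artifactual signatures include high-frequency power above 0.1 Hz,
   spikes, and sawtooth patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats
from scipy.optimize import linear_sum_assignment
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import (
    DegenerateSeriesError,
    InfeasibleMatchError,
    InvalidArgumentError,
)
from .timecourses import RSN_LABELS

__all__ = [
    "SpatialComponentSet",
    "TemplateSet",
    "MatchResult",
    "Fingerprint",
    "FINGERPRINT_BANDS",
    "default_templates",
    "goodness_of_fit",
    "match_templates",
    "compute_fingerprint",
    "train_neuronal_classifier",
    "classify_neuronal",
]

#: Frequency band edges (Hz) of the five spectral fingerprint features.
FINGERPRINT_BANDS: tuple[float, ...] = (0.0, 0.008, 0.02, 0.05, 0.1, 0.25)

#: |z| threshold and connectivity used by the degree-of-clustering feature.
CLUSTER_Z_THRESHOLD = 1.5


@dataclass
class SpatialComponentSet:
    """Independent-component spatial maps on a common voxel grid."""

    maps: np.ndarray  # (n_components, *grid)
    ids: list[str]
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    source: list[str] | None = None  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim < 2:
            raise InvalidArgumentError("maps must be (n_components, *grid)")
        if len(self.ids) != self.maps.shape[0]:
            raise InvalidArgumentError("one id per component required")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    @property
    def grid(self) -> tuple[int, ...]:
        return self.maps.shape[1:]


@dataclass
class TemplateSet:
    """Named binary RSN masks on the component grid."""

    names: list[str]
    masks: np.ndarray  # (n_templates, *grid), boolean

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if len(self.names) != self.masks.shape[0]:
            raise InvalidArgumentError("one name per mask required")
        for name, mask in zip(self.names, self.masks):
            if not mask.any():
                raise InvalidArgumentError(f"template {name!r} is empty")

    @property
    def grid(self) -> tuple[int, ...]:
        return self.masks.shape[1:]


@dataclass
class MatchResult:
    """Injective template -> component assignment with per-match scores."""

    mapping: dict[str, str]
    goodness: dict[str, float]
    unmatched: list[str]


def default_templates(grid: tuple[int, int, int] = (32, 32, 16)) -> TemplateSet:
    """Ten ellipsoidal toy-space masks, one per canonical RSN.

    Centers are spread deterministically over the grid so no two masks
    overlap more than marginally; intended for synthetic benchmarks, not
    for standard-space analysis.
    """
    rng = np.random.default_rng(20201018)  # fixed layout, not a tunable
    coords = np.indices(grid)
    masks = []
    centers = []
    for _ in RSN_LABELS:
        for _ in range(200):
            c = np.array([rng.uniform(0.2, 0.8) * g for g in grid])
            if all(np.linalg.norm(c - p) >= 0.28 * min(grid) for p in centers):
                break
        centers.append(c)
        radii = np.array([0.14 * g for g in grid])
        d2 = sum(((coords[a] - centers[-1][a]) / radii[a]) ** 2 for a in range(3))
        masks.append(d2 <= 1.0)
    return TemplateSet(names=list(RSN_LABELS), masks=np.stack(masks))


def goodness_of_fit(component_map: np.ndarray, template_mask: np.ndarray) -> float:
    """Inside-mask minus outside-mask mean of absolute amplitudes.

    Uses absolute amplitudes so the score is invariant to the arbitrary
    sign of an independent component.  Higher is better; a constant map
    scores exactly 0.
    """
    component_map = np.asarray(component_map, dtype=float)
    template_mask = np.asarray(template_mask, dtype=bool)
    if component_map.shape != template_mask.shape:
        raise InvalidArgumentError("component map and template must share a grid")
    if not template_mask.any():
        raise InvalidArgumentError("template mask is empty")
    if template_mask.all():
        raise InvalidArgumentError("template mask covers the whole grid")
    a = np.abs(component_map)
    return float(a[template_mask].mean() - a[~template_mask].mean())


def match_templates(
    components: SpatialComponentSet, templates: TemplateSet
) -> MatchResult:
    """Optimal injective assignment of every template to a component.

    Maximizes the total goodness-of-fit over all injective assignments
    (optimal linear assignment on the template x component score matrix),
    honouring the two matching constraints: every template is assigned,
    and no component is claimed twice.  Templates are processed in name
    order so exact ties resolve deterministically.
    """
    if components.grid != templates.grid:
        raise InvalidArgumentError("components and templates must share a grid")
    if components.n_components < len(templates.names):
        raise InfeasibleMatchError(
            f"{components.n_components} components for {len(templates.names)} templates"
        )
    order = np.argsort(np.asarray(templates.names, dtype=object))
    gof = np.empty((len(templates.names), components.n_components))
    for row, t_idx in enumerate(order):
        for c in range(components.n_components):
            gof[row, c] = goodness_of_fit(
                components.maps[c], templates.masks[t_idx]
            )
    rows, cols = linear_sum_assignment(-gof)
    mapping: dict[str, str] = {}
    goodness: dict[str, float] = {}
    for r, c in zip(rows, cols):
        name = templates.names[order[r]]
        mapping[name] = components.ids[c]
        goodness[name] = float(gof[r, c])
    claimed = set(mapping.values())
    unmatched = [cid for cid in components.ids if cid not in claimed]
    return MatchResult(mapping=mapping, goodness=goodness, unmatched=unmatched)


@dataclass
class Fingerprint:
    """11-feature spatio-temporal descriptor of an independent component.

    Spatial features describe the amplitude distribution of the map;
    temporal features describe the associated time-course.  Band powers
    are fractions of total spectral power within 0-0.25 Hz and sum to 1.
    """

    degree_of_clustering: float
    skewness: float
    kurtosis: float  # excess (normal = 0)
    spatial_entropy: float  # nats
    one_lag_autocorrelation: float
    temporal_entropy: float  # nats
    band_power: np.ndarray  # 5 fractions over FINGERPRINT_BANDS

    FEATURE_NAMES = (
        "degree_of_clustering",
        "skewness",
        "kurtosis",
        "spatial_entropy",
        "one_lag_autocorrelation",
        "temporal_entropy",
        "band_power_0.000-0.008Hz",
        "band_power_0.008-0.020Hz",
        "band_power_0.020-0.050Hz",
        "band_power_0.050-0.100Hz",
        "band_power_0.100-0.250Hz",
    )

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                [
                    self.degree_of_clustering,
                    self.skewness,
                    self.kurtosis,
                    self.spatial_entropy,
                    self.one_lag_autocorrelation,
                    self.temporal_entropy,
                ],
                self.band_power,
            ]
        )


def _histogram_entropy(values: np.ndarray) -> float:
    """Shannon entropy (nats) of a ceil(sqrt(n))-bin equal-width histogram."""
    values = np.asarray(values, dtype=float).ravel()
    if np.ptp(values) == 0:
        raise DegenerateSeriesError("constant data: entropy is undefined")
    n_bins = math.ceil(math.sqrt(values.size))
    counts, _ = np.histogram(values, bins=n_bins)
    p = counts[counts > 0] / values.size
    return float(-(p * np.log(p)).sum())


def _degree_of_clustering(spatial_map: np.ndarray) -> float:
    """Fraction of suprathreshold voxels in the largest connected cluster.

    Voxels with |z| > 1.5 (z-scored within the map) are labelled with
    6-connectivity (faces only); returns (largest cluster size) /
    (suprathreshold count), or 0 when nothing survives the threshold.
    """
    m = np.asarray(spatial_map, dtype=float)
    sd = m.std()
    if sd == 0:
        raise DegenerateSeriesError("constant spatial map")
    z = (m - m.mean()) / sd
    supra = np.abs(z) > CLUSTER_Z_THRESHOLD
    total = int(supra.sum())
    if total == 0:
        return 0.0
    labelled, n_clusters = ndimage.label(supra)  # default structure: faces only
    sizes = ndimage.sum_labels(supra, labelled, index=np.arange(1, n_clusters + 1))
    return float(sizes.max() / total)


def _band_power_fractions(
    tc: np.ndarray, sampling_interval: float
) -> np.ndarray:
    """Power fractions over the five fingerprint bands, normalized within
    0-0.25 Hz (averaged-periodogram spectral estimate)."""
    fs = 1.0 / sampling_interval
    nperseg = min(tc.size, 128)
    freqs, psd = signal.welch(tc, fs=fs, nperseg=nperseg, detrend="constant")
    edges = np.asarray(FINGERPRINT_BANDS)
    in_range = (freqs > 0) & (freqs <= edges[-1] + 1e-12)
    total = psd[in_range].sum()
    if total <= 0:
        raise DegenerateSeriesError("no spectral power in 0-0.25 Hz")
    fractions = np.empty(len(edges) - 1)
    for b in range(len(edges) - 1):
        sel = in_range & (freqs > edges[b]) & (freqs <= edges[b + 1] + 1e-12)
        fractions[b] = psd[sel].sum() / total
    return fractions


def compute_fingerprint(
    time_course: np.ndarray,
    spatial_map: np.ndarray,
    sampling_interval: float = 2.0,
) -> Fingerprint:
    """Compute the 11-element fingerprint of one component.

    Spatial statistics (degree of clustering, skewness, excess kurtosis,
    histogram entropy) are taken over all voxels of the map; temporal
    statistics over the time-course.  Band-power fractions are invariant
    to positive rescaling of the time-course.
    """
    tc = np.asarray(time_course, dtype=float).ravel()
    if tc.size < 32:
        raise InvalidArgumentError("time-course must have >= 32 samples")
    if np.ptp(tc) == 0:
        raise DegenerateSeriesError(
            "constant time-course: autocorrelation/entropy undefined"
        )
    m = np.asarray(spatial_map, dtype=float)
    vox = m.ravel()
    r = np.corrcoef(tc[:-1], tc[1:])[0, 1]
    return Fingerprint(
        degree_of_clustering=_degree_of_clustering(m),
        skewness=float(stats.skew(vox)),
        kurtosis=float(stats.kurtosis(vox, fisher=True)),
        spatial_entropy=_histogram_entropy(vox),
        one_lag_autocorrelation=float(np.clip(r, -1.0, 1.0)),
        temporal_entropy=_histogram_entropy(tc),
        band_power=_band_power_fractions(tc, sampling_interval),
    )


NEURONAL, ARTIFACTUAL = "neuronal", "artifactual"


def train_neuronal_classifier(
    fingerprints: list[Fingerprint], labels: list[str]
) -> Pipeline:
    """Fit a linear maximum-margin classifier on standardized fingerprints.

    Both classes must be present.  Returns a fitted pipeline
    (standardizer + linear SVM) accepted by :func:`classify_neuronal`.
    """
    if len(fingerprints) != len(labels):
        raise InvalidArgumentError("one label per fingerprint required")
    classes = set(labels)
    if classes != {NEURONAL, ARTIFACTUAL}:
        raise InvalidArgumentError(
            f"training data must contain both classes, got {sorted(classes)}"
        )
    X = np.stack([fp.to_vector() for fp in fingerprints])
    model = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=1.0))]
    )
    model.fit(X, np.asarray(labels))
    return model


def classify_neuronal(fingerprint: Fingerprint, model: Pipeline) -> tuple[str, float]:
    """Label one fingerprint; returns (label, signed margin).

    The margin is the signed distance to the separating hyperplane,
    positive toward the neuronal side.
    """
    x = fingerprint.to_vector()[None, :]
    margin = float(model.decision_function(x)[0])
    classes = list(model.named_steps["svm"].classes_)
    # decision_function is positive toward classes_[1]
    if classes[1] != NEURONAL:
        margin = -margin
    label = NEURONAL if margin > 0 else ARTIFACTUAL
    return label, margin
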