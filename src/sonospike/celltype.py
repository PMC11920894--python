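"""Waveform-based classification of units into fast- vs regular-spiking.

Extracellular action potentials of putative inhibitory interneurons
(fast-spiking units, FSU) are narrower than those of putative excitatory
pyramidal neurons (regular-spiking units, RSU). Units are clustered by
k-means (k = 2) on the two phase durations — initial phase (IP) and
after-hyperpolarization phase (AHP), both in ms and used unstandardized —
and the cluster with the smaller mean total duration is labeled FSU.

Units sitting ambiguously between the two centroids (nearer/farther
centroid distance ratio above ``ambiguity_thresh``) are re-assigned by
firing rate: fast-spiking cells typically sustain higher rates, so
``mean_rate >= rate_cutoff`` maps to FSU and lower rates to RSU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans


class ClassificationError(ValueError):
    """Clustering is impossible or degenerate for the given features."""


@dataclass(frozen=True)
class UnitLabel:
    """Cell-type assignment for one unit."""

    unit_id: str
    label: str  # "RSU" | "FSU"
    boundary_flag: bool
    distance_ratio: float  # nearer/farther centroid distance, in [0, 1]


def classify(
    features: list[tuple[str, float, float, float]],
    seed: int = 0,
    ambiguity_thresh: float = 0.8,
    rate_cutoff: float = 10.0,
) -> list[UnitLabel]:
    """Assign FSU/RSU labels from (unit_id, ip_ms, ahp_ms, mean_rate) rows.

    K-means with k = 2 and 10 restarts on the duration features; the
    smaller-duration cluster is FSU. Units with distance ratio above
    ``ambiguity_thresh`` are re-labeled by the rate tie-break.
    Deterministic per seed.
    """
    if len(features) < 2:
        raise ClassificationError("need at least 2 units to cluster")
    ids = [f[0] for f in features]
    X = np.array([[f[1], f[2]] for f in features], dtype=float)
    rates = np.array([f[3] for f in features], dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(rates)):
        raise ClassificationError("non-finite feature values")
    if np.allclose(X, X[0]):
        raise ClassificationError("identical features for all units; clustering degenerate")

    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
    centroids = km.cluster_centers_
    fsu_cluster = int(np.argmin(centroids.sum(axis=1)))

    d = np.linalg.norm(X[:, None, :] - centroids[None, :, :], axis=2)
    d_near = d.min(axis=1)
    d_far = d.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(d_far > 0, d_near / d_far, 1.0)

    labels: list[UnitLabel] = []
    for i, uid in enumerate(ids):
        boundary = bool(ratio[i] > ambiguity_thresh)
        if boundary:
            lab = "FSU" if rates[i] >= rate_cutoff else "RSU"
        else:
            lab = "FSU" if km.labels_[i] == fsu_cluster else "RSU"
        labels.append(
            UnitLabel(
                unit_id=uid,
                label=lab,
                boundary_flag=boundary,
                distance_ratio=float(ratio[i]),
            )
        )
    return labels
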