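"""Expression matrices, RPKM normalization, and temporal k-means clustering.

Counts are stored as a transcripts × samples DataFrame alongside a sample
sheet carrying per-sample metadata (timepoint in hours post-fertilization,
or dissection region and replicate). RPKM divides counts by transcript
length in kb and library size in millions. Temporal profiles are
max-normalized per transcript and clustered with Euclidean k-means into
k=8 groups, relabeled deterministically by centroid peak time so cluster 1
is the earliest (maternal) shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Transcripts × samples expression values with sample metadata.

    values: DataFrame indexed by transcript id, columns = sample ids.
    samples: DataFrame indexed by sample id; for time courses it has a
        ``time`` column (hours), for spatial designs ``region`` and
        ``replicate`` columns.
    units: "counts" or "rpkm".
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    units: str = "counts"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)[:5]}")

    @property
    def times(self) -> np.ndarray:
        return self.samples.loc[self.values.columns, "time"].to_numpy(dtype=float)

    def subset(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(ids)], self.samples, self.units)

    def to_tsv(self, values_path: str, samples_path: str | None = None) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="transcript_id")
        if samples_path:
            self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, values_path: str, samples_path: str, units: str = "counts"):
        values = pd.read_csv(values_path, sep="\t", index_col="transcript_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(values, samples, units)


def rpkm(counts: ExpressionMatrix, transcript_lengths: dict[str, int],
         library_sizes: pd.Series | None = None) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm = count / (length_kb × library_size_millions). Library sizes default
    to the per-sample column totals.
    """
    missing = [tid for tid in counts.values.index if tid not in transcript_lengths]
    if missing:
        raise KeyError(f"no transcript length for {missing[0]!r} "
                       f"({len(missing)} transcripts missing)")
    lengths = np.array([transcript_lengths[t] for t in counts.values.index], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be > 0")
    if library_sizes is None:
        library_sizes = counts.values.sum(axis=0)
    lib = library_sizes.loc[counts.values.columns].to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    vals = counts.values.to_numpy(dtype=float) / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
    out = pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(out, counts.samples, units="rpkm")


def max_normalize(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Divide each row by its maximum; all-zero rows are excluded and returned.

    Kept rows lie in [0, 1] with row maximum exactly 1.
    """
    maxima = profiles.max(axis=1)
    zero = maxima <= 0
    excluded = list(profiles.index[zero].astype(str))
    if excluded:
        logger.info("max_normalize: excluding %d all-zero profiles", len(excluded))
    kept = profiles.loc[~zero]
    return kept.div(maxima[~zero], axis=0), excluded


@dataclass
class ClusterResult:
    """k-means assignment of temporal profiles, clusters labeled 1..k by peak time."""

    k: int
    assignments: pd.Series  # transcript id -> cluster label (1-based)
    centroids: pd.DataFrame  # k × T, index = cluster label
    inertia: float
    cluster_means: pd.DataFrame = field(default=None)

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def cluster_profiles(normalized: pd.DataFrame, k: int = 8, seed: int = 0,
                     n_init: int = 25) -> ClusterResult:
    """Euclidean k-means over max-normalized profiles, deterministic relabeling.

    Uses k-means++ seeding with `n_init` restarts from a fixed seed; clusters
    are renumbered by ascending centroid peak time (argmax column), ties by
    centroid mean, so labels are reproducible and ordered from earliest-
    peaking (maternal-like) to latest.
    """
    if len(normalized) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(normalized)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(normalized.values)
    centroids = km.cluster_centers_
    peak = centroids.argmax(axis=1)
    order = sorted(range(k), key=lambda i: (peak[i], centroids[i].mean(), i))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[l] for l in raw_labels], index=normalized.index,
                       name="cluster")
    cent = pd.DataFrame(centroids[order], index=range(1, k + 1),
                        columns=normalized.columns)
    means = normalized.groupby(labels).mean()
    return ClusterResult(k=k, assignments=labels, centroids=cent,
                         inertia=float(km.inertia_), cluster_means=means)
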