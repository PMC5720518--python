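"""Phase 1: within-bin click clustering and summary-node extraction.

Detections are grouped into clock-aligned 5-minute bins.  Bins with
fewer than 100 clicks are dropped (too few for a representative
spectral sample) and bins with more than 5,000 clicks are uniformly
subsampled to 5,000 (pairwise comparison is O(n^2)).  Within each bin a
spectral-similarity network is built, pruned at ``p_e`` (default 0.95)
and clustered with Chinese Whispers; every cluster of at least 100
clicks is condensed into a *summary node* — the mean dB spectrum of its
members plus the distribution and mode of their inter-click intervals
(ICIs).  Summary nodes are the atoms of the cross-bin Phase 2
clustering.

ICIs are first differences between sequential clicks in one cluster,
histogrammed between 0.01 and 0.5 s in 10-ms steps.  When interleaved
click trains from several animals saturate the lowest ICI bins, the
modal ICI is taken as the first local peak of the distribution rather
than the global mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import CWConfig, chinese_whispers
from .io import DetectionTable
from .similarity import normalize_spectra, prune_network, spectral_similarity

__all__ = [
    "ICI_BIN_EDGES",
    "TimeBin",
    "ICIDistribution",
    "SummaryNode",
    "EncounterSummary",
    "assemble_bins",
    "compute_encounters",
    "ici_distribution",
    "modal_ici",
    "cluster_bin",
    "summarize",
]

#: ICI histogram grid: 0.01-0.5 s in 10-ms increments (49 bins).
ICI_BIN_EDGES = np.round(np.arange(0.01, 0.5001, 0.01), 10)


@dataclass
class TimeBin:
    """All detections falling in one 5-minute window (one site/deployment)."""

    bin_start: float                  # epoch seconds, clock-aligned
    duration_s: float
    times: np.ndarray                 # (n,) click times, sorted
    spectra: np.ndarray               # (n, n_bins) dB
    frequencies_khz: np.ndarray
    site_id: str
    deployment_id: str
    source_indices: np.ndarray | None = None  # rows of the originating table

    @property
    def n_clicks(self) -> int:
        return len(self.times)


@dataclass
class ICIDistribution:
    """Histogram of inter-click intervals on the fixed 10-ms grid."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def modal(self) -> float:
        return modal_ici(self)

    @classmethod
    def from_times(cls, times: np.ndarray) -> "ICIDistribution":
        """Histogram the first differences of time-sorted click times.

        Intervals outside [0.01, 0.5) s are excluded.  Fewer than two
        clicks yield an empty (all-zero) distribution.
        """
        times = np.sort(np.asarray(times, dtype=float))
        if times.size < 2:
            return cls(bin_edges=ICI_BIN_EDGES, counts=np.zeros(len(ICI_BIN_EDGES) - 1, dtype=int))
        icis = np.diff(times)
        icis = icis[(icis >= ICI_BIN_EDGES[0]) & (icis < ICI_BIN_EDGES[-1])]
        counts, _ = np.histogram(icis, bins=ICI_BIN_EDGES)
        return cls(bin_edges=ICI_BIN_EDGES, counts=counts.astype(int))


def ici_distribution(times: np.ndarray) -> ICIDistribution:
    """Inter-click-interval distribution of one within-bin cluster."""
    return ICIDistribution.from_times(times)


def modal_ici(dist: ICIDistribution) -> float:
    """Modal ICI: histogram-mode bin center, with a saturation guard.

    Default is the global argmax (ties to the lower bin).  When dense,
    interleaved clicking saturates the low end — the global argmax lies
    in the lowest three bins while counts decline monotonically across
    them — the first local maximum (a bin strictly greater than both
    neighbors) is used instead, falling back to the global argmax when
    no such peak exists.
    """
    counts = np.asarray(dist.counts)
    if counts.sum() == 0:
        raise ValueError("modal ICI undefined for an empty distribution")
    centers = dist.bin_centers
    amax = int(np.argmax(counts))
    saturated = amax <= 2 and counts[0] >= counts[1] >= counts[2]
    if saturated:
        for i in range(1, len(counts) - 1):
            if counts[i] > counts[i - 1] and counts[i] > counts[i + 1]:
                return float(centers[i])
    return float(centers[amax])


@dataclass
class SummaryNode:
    """Per-bin aggregate of one within-bin click cluster.

    The unit of Phase 2 clustering: the cluster's mean dB spectrum, its
    ICI distribution and modal ICI, and bookkeeping for provenance.
    ``modal_ici`` is None when the cluster produced no in-range ICIs.
    """

    site_id: str
    deployment_id: str
    bin_start: float
    n_clicks: int
    frequencies_khz: np.ndarray
    mean_spectrum: np.ndarray         # dB over 10-70 kHz
    ici: ICIDistribution
    modal_ici: float | None
    member_indices: np.ndarray | None = None  # rows of the originating table

    @property
    def peak_frequency_khz(self) -> float:
        return float(self.frequencies_khz[int(np.argmax(self.mean_spectrum))])


@dataclass
class EncounterSummary:
    """A run of detections bounded by >= 15 min without clicks."""

    start: float
    end: float
    n_clicks: int

    @property
    def duration_min(self) -> float:
        return (self.end - self.start) / 60.0


def compute_encounters(times: np.ndarray, gap_min: float = 15.0) -> list[EncounterSummary]:
    """Split a time-sorted detection stream into encounters.

    Encounters are maximal runs with inter-detection gaps strictly less
    than ``gap_min`` minutes; a gap of exactly ``gap_min`` starts a new
    encounter.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return []
    gap_s = gap_min * 60.0
    breaks = np.flatnonzero(np.diff(times) >= gap_s) + 1
    out = []
    for seg in np.split(times, breaks):
        out.append(EncounterSummary(start=float(seg[0]), end=float(seg[-1]), n_clicks=len(seg)))
    return out


def assemble_bins(table: DetectionTable, *, bin_duration_s: float = 300.0,
                  min_clicks: int = 100, max_clicks: int = 5000,
                  rng_seed: int = 0) -> list[TimeBin]:
    """Group detections into clock-aligned bins, applying floor and cap.

    Bins with fewer than ``min_clicks`` detections are dropped; bins with
    more than ``max_clicks`` are uniformly subsampled to exactly
    ``max_clicks`` (seeded, time order preserved).  Bins are grouped per
    (site, deployment) so simultaneous recordings never mix.
    """
    if len(table) == 0:
        return []
    order = np.lexsort((table.times, table.deployment_id, table.site_id))
    bins: list[TimeBin] = []
    bin_idx = np.floor(table.times / bin_duration_s).astype(np.int64)
    keys = list(zip(table.site_id[order], table.deployment_id[order], bin_idx[order]))

    # contiguous grouping over the sorted keys
    start = 0
    groups: list[tuple[tuple, np.ndarray]] = []
    for k in range(1, len(keys) + 1):
        if k == len(keys) or keys[k] != keys[start]:
            groups.append((keys[start], order[start:k]))
            start = k

    for gnum, ((site, dep, b), idx) in enumerate(groups):
        if len(idx) < min_clicks:
            continue
        idx = idx[np.argsort(table.times[idx], kind="stable")]
        if len(idx) > max_clicks:
            rng = np.random.default_rng([rng_seed, gnum])
            sel = rng.choice(len(idx), size=max_clicks, replace=False)
            idx = idx[np.sort(sel)]
        bins.append(TimeBin(
            bin_start=float(b) * bin_duration_s,
            duration_s=bin_duration_s,
            times=table.times[idx],
            spectra=table.spectra[idx],
            frequencies_khz=table.frequencies_khz,
            site_id=str(site),
            deployment_id=str(dep),
            source_indices=idx,
        ))
    return bins


def cluster_bin(bin: TimeBin, p_e: float = 0.95, *, min_cluster_size: int = 100,
                rng_seed: int = 0, max_iterations: int = 20) -> list[SummaryNode]:
    """Cluster one bin's click spectra and emit summary nodes.

    Builds the within-bin spectral similarity network, prunes the weakest
    ``p_e`` fraction of edges, runs Chinese Whispers, and condenses each
    cluster of at least ``min_cluster_size`` clicks into a SummaryNode
    (mean of member dB spectra; ICI distribution over the time-sorted
    member clicks of that cluster only).
    """
    norm, valid = normalize_spectra(bin.spectra)
    if not valid.all():
        warnings.warn(
            f"bin {bin.site_id}@{bin.bin_start:.0f}: dropped "
            f"{int((~valid).sum())} constant-spectrum click(s)", stacklevel=2)
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        return []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate pairs become NaN edges
        sim = spectral_similarity(norm[idx])
    net = prune_network(sim, p_e, node_ids=idx)
    part = chinese_whispers(net, CWConfig(max_iterations=max_iterations, rng_seed=rng_seed))

    nodes: list[SummaryNode] = []
    clusters = sorted(part.clusters().items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    for _, members in clusters:
        if len(members) < min_cluster_size:
            continue
        members = np.asarray(members, dtype=int)
        times = np.sort(bin.times[members])
        ici = ICIDistribution.from_times(times)
        nodes.append(SummaryNode(
            site_id=bin.site_id,
            deployment_id=bin.deployment_id,
            bin_start=bin.bin_start,
            n_clicks=len(members),
            frequencies_khz=bin.frequencies_khz,
            mean_spectrum=bin.spectra[members].mean(axis=0),
            ici=ici,
            modal_ici=modal_ici(ici) if ici.total > 0 else None,
            member_indices=(None if bin.source_indices is None
                            else bin.source_indices[members]),
        ))
    return nodes


def summarize(table: DetectionTable, *, p_e: float = 0.95,
              bin_duration_s: float = 300.0, min_clicks: int = 100,
              max_clicks: int = 5000, min_cluster_size: int = 100,
              max_iterations: int = 20, rng_seed: int = 0) -> list[SummaryNode]:
    """Full Phase 1 pass: assemble bins, cluster each, collect summary nodes.

    Per-bin clustering seeds are derived deterministically from
    ``rng_seed`` and the bin's position in (site, deployment, time)
    order, so results are independent of click order within the table.
    """
    bins = assemble_bins(table, bin_duration_s=bin_duration_s,
                         min_clicks=min_clicks, max_clicks=max_clicks,
                         rng_seed=rng_seed)
    nodes: list[SummaryNode] = []
    for k, b in enumerate(bins):
        seed = np.random.SeedSequence([rng_seed, 1, k]).generate_state(1)[0] % (2**31)
        nodes.extend(cluster_bin(b, p_e, min_cluster_size=min_cluster_size,
                                 rng_seed=int(seed), max_iterations=max_iterations))
    return nodes
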