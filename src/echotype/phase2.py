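"""Phase 2: discovery of recurrent click types across time bins.

Summary nodes from Phase 1 are sampled evenly across sites (default
1,000 per site), connected by the combined similarity
``S2 = S_ICI * S_SPEC`` over their normalized mean spectra and modal
ICIs, pruned at ``p_e`` (default 0.95), and clustered with 20
independent Chinese Whispers runs.  Clusters smaller than 20 nodes are
dropped from each run; the run with the highest mean pairwise NMI
against all others is kept ("Best of K"), and each of its surviving
clusters becomes a click-type template: mean normalized spectrum with
25th/75th percentile envelopes, the pooled ICI histogram of its member
bins, and peak-frequency / modal-ICI statistics.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import CWConfig, Partition, best_of_k, chinese_whispers
from .phase1 import ICIDistribution, SummaryNode, TimeBin, modal_ici
from .similarity import (combined_similarity, ici_similarity, normalize_spectra,
                         prune_network, spectral_similarity)

__all__ = [
    "Phase2Config",
    "ClickTypeTemplate",
    "DiscoveryResult",
    "sample_summary_nodes",
    "build_phase2_network",
    "discover_types",
    "pe_sweep_bins",
    "pe_sweep_nodes",
]


@dataclass
class Phase2Config:
    nodes_per_site: int = 1000
    n_runs: int = 20
    p_e: float = 0.95
    min_cluster_size: int = 20
    max_iterations: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.nodes_per_site, self.n_runs, self.min_cluster_size, self.max_iterations) < 1:
            raise ValueError("Phase2Config values must be positive")


@dataclass
class ClickTypeTemplate:
    """One discovered click type: the target of template classification."""

    label: str
    members: list                     # member SummaryNodes
    frequencies_khz: np.ndarray
    mean_spectrum: np.ndarray         # mean of member normalized spectra
    p25_spectrum: np.ndarray
    p75_spectrum: np.ndarray
    ici_counts: np.ndarray            # pooled member ICI histograms
    modal_ici: float | None           # mode of the pooled distribution
    peak_frequency_mean_khz: float
    peak_frequency_cv: float
    modal_ici_mean_s: float
    modal_ici_cv: float

    @property
    def cluster_size(self) -> int:
        return len(self.members)


@dataclass
class DiscoveryResult:
    partition: Partition              # Best-of-K partition (filtered)
    templates: list[ClickTypeTemplate]
    nodes: list                       # the sampled nodes the network was built on
    diagnostics: dict


def sample_summary_nodes(nodes_by_site: dict, config: Phase2Config) -> list[SummaryNode]:
    """Uniform per-site sample so sites are evenly represented.

    Sites offering fewer than ``nodes_per_site`` nodes contribute all of
    them (with a warning).  Seeded and deterministic: sites are visited
    in sorted order.
    """
    if not nodes_by_site:
        raise ValueError("no summary nodes supplied")
    rng = np.random.default_rng(config.rng_seed)
    out: list[SummaryNode] = []
    for site in sorted(nodes_by_site):
        pool = list(nodes_by_site[site])
        if len(pool) <= config.nodes_per_site:
            if len(pool) < config.nodes_per_site:
                warnings.warn(
                    f"site {site}: only {len(pool)} summary nodes available "
                    f"(< {config.nodes_per_site}); using all", stacklevel=2)
            out.extend(pool)
        else:
            sel = np.sort(rng.choice(len(pool), size=config.nodes_per_site, replace=False))
            out.extend(pool[i] for i in sel)
    return out


def build_phase2_network(nodes: list[SummaryNode], p_e: float = 0.95):
    """Combined-similarity network over summary nodes, pruned at ``p_e``.

    Node spectra are min-max normalized at comparison time; nodes with an
    undefined modal ICI (or a degenerate spectrum) are excluded with a
    warning.  Returns ``(network, used_indices)`` where node ids in the
    network index into ``nodes``.
    """
    spectra = np.vstack([n.mean_spectrum for n in nodes])
    norm, valid = normalize_spectra(spectra)
    has_ici = np.array([n.modal_ici is not None for n in nodes])
    usable = valid & has_ici
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} summary node(s) without a "
            "modal ICI or with a degenerate spectrum", stacklevel=2)
    idx = np.flatnonzero(usable)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s_spec = spectral_similarity(norm[idx])
    icis = np.array([nodes[i].modal_ici for i in idx], dtype=float)
    s_ici = ici_similarity(icis[:, None], icis[None, :])
    s2 = combined_similarity(s_spec, s_ici)
    return prune_network(s2, p_e, node_ids=idx), idx


def _label_sequence(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for k in range(n):
        lab = ""
        k0 = k
        while True:
            lab = letters[k0 % 26] + lab
            k0 = k0 // 26 - 1
            if k0 < 0:
                break
        out.append(lab)
    return out


def _build_template(label: str, members: list[SummaryNode],
                    frequencies_khz: np.ndarray) -> ClickTypeTemplate:
    norm, valid = normalize_spectra(np.vstack([m.mean_spectrum for m in members]))
    norm = norm[valid]
    pooled = np.sum([m.ici.counts for m in members], axis=0).astype(int)
    pooled_dist = ICIDistribution(bin_edges=members[0].ici.bin_edges, counts=pooled)
    peak_f = np.array([m.peak_frequency_khz for m in members])
    m_ici = np.array([m.modal_ici for m in members], dtype=float)
    return ClickTypeTemplate(
        label=label,
        members=list(members),
        frequencies_khz=frequencies_khz,
        mean_spectrum=norm.mean(axis=0),
        p25_spectrum=np.percentile(norm, 25, axis=0),
        p75_spectrum=np.percentile(norm, 75, axis=0),
        ici_counts=pooled,
        modal_ici=modal_ici(pooled_dist) if pooled.sum() > 0 else None,
        peak_frequency_mean_khz=float(peak_f.mean()),
        peak_frequency_cv=float(peak_f.std() / peak_f.mean()) if peak_f.mean() else 0.0,
        modal_ici_mean_s=float(m_ici.mean()),
        modal_ici_cv=float(m_ici.std() / m_ici.mean()) if m_ici.mean() else 0.0,
    )


def discover_types(nodes: list[SummaryNode], config: Phase2Config | None = None
                   ) -> DiscoveryResult:
    """Consensus click-type discovery over a set of summary nodes.

    Runs Chinese Whispers ``n_runs`` times on the pruned combined-
    similarity network, drops clusters below ``min_cluster_size`` from
    each run, selects the Best-of-K partition by mean pairwise NMI
    (computed on the nodes labeled in both runs of each pair), and emits
    one template per surviving cluster.  Template labels (A, B, ...) are
    assigned by descending modal ICI, then ascending peak frequency.
    """
    config = config or Phase2Config()
    if len(nodes) < config.min_cluster_size:
        raise ValueError(
            f"need at least {config.min_cluster_size} summary nodes, got {len(nodes)}")
    net, used = build_phase2_network(nodes, config.p_e)
    if net.n_edges == 0:
        raise ValueError("network fully isolated after pruning; nothing to cluster")

    partitions, raw_cluster_counts, isolation = [], [], []
    ss = np.random.SeedSequence(config.rng_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_runs)]
    for seed in seeds:
        part = chinese_whispers(net, CWConfig(max_iterations=config.max_iterations,
                                              rng_seed=seed))
        raw_cluster_counts.append(part.k)
        filtered = part.drop_small_clusters(config.min_cluster_size)
        partitions.append(filtered)
        isolation.append(1.0 - (filtered.n / len(used) if used.size else 0.0))

    chosen, chosen_idx, nmi_matrix = best_of_k(partitions, restrict_to_common=True)

    clusters = sorted(chosen.clusters().values(), key=lambda m: m[0])
    unlabeled = [_build_template("?", [nodes[i] for i in members], nodes[0].frequencies_khz)
                 for members in clusters]
    unlabeled.sort(key=lambda t: (-(t.modal_ici if t.modal_ici is not None else -1.0),
                                  t.peak_frequency_mean_khz))
    templates = []
    for lab, t in zip(_label_sequence(len(unlabeled)), unlabeled):
        t.label = lab
        templates.append(t)

    k = config.n_runs
    mean_nmi = float((nmi_matrix.sum() - k) / (k * (k - 1))) if k > 1 else 1.0
    diagnostics = {
        "nmi_matrix": nmi_matrix,
        "mean_pairwise_nmi": mean_nmi,
        "clusters_per_run": raw_cluster_counts,
        "retained_fraction_per_run": [1.0 - f for f in isolation],
        "isolation_fraction_pruning": net.isolation_fraction,
        "chosen_run": chosen_idx,
        "n_nodes_sampled": len(nodes),
        "n_nodes_networked": int(used.size),
        "config": config,
    }
    return DiscoveryResult(partition=chosen, templates=templates,
                           nodes=nodes, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# exploratory p_e sweeps

def pe_sweep_bins(bins: list[TimeBin], pe_values, *, min_cluster_size: int = 100,
                  rng_seed: int = 0) -> pd.DataFrame:
    """Phase-1-mode pruning sweep: clusters/bin, isolation, within-cluster similarity.

    For each ``p_e``, every bin is clustered and three operator
    diagnostics are reported: the mean number of clusters (of any size)
    per bin, the mean percentage of nodes isolated by pruning, and the
    mean surviving within-cluster edge weight.
    """
    rows = []
    for p_e in pe_values:
        n_clusters, isolated, within = [], [], []
        for k, b in enumerate(bins):
            norm, valid = normalize_spectra(b.spectra)
            idx = np.flatnonzero(valid)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sim = spectral_similarity(norm[idx])
            net = prune_network(sim, p_e, node_ids=np.arange(idx.size))
            part = chinese_whispers(net, CWConfig(rng_seed=rng_seed + k))
            n_clusters.append(part.k)
            isolated.append(net.isolation_fraction)
            if net.n_edges:
                labels = part.labels
                same = [w for i, j, w in zip(net.edges_i, net.edges_j, net.weights)
                        if labels.get(i) == labels.get(j)]
                if same:
                    within.append(float(np.mean(same)))
        rows.append({
            "p_e": p_e,
            "mean_clusters_per_bin": float(np.mean(n_clusters)) if n_clusters else 0.0,
            "pct_isolated": 100.0 * float(np.mean(isolated)) if isolated else 0.0,
            "mean_within_cluster_similarity": float(np.mean(within)) if within else np.nan,
        })
    return pd.DataFrame(rows)


def pe_sweep_nodes(nodes: list[SummaryNode], pe_values, *, n_runs: int = 20,
                   min_cluster_size: int = 20, rng_seed: int = 0) -> pd.DataFrame:
    """Phase-2-mode pruning sweep: cluster count, isolation, NMI consistency."""
    rows = []
    for p_e in pe_values:
        cfg = Phase2Config(n_runs=n_runs, p_e=p_e,
                           min_cluster_size=min_cluster_size, rng_seed=rng_seed)
        net, used = build_phase2_network(nodes, p_e)
        parts, ks = [], []
        ss = np.random.SeedSequence(rng_seed)
        for s in ss.spawn(n_runs):
            part = chinese_whispers(net, CWConfig(rng_seed=int(s.generate_state(1)[0] % 2**31)))
            ks.append(part.k)
            parts.append(part.drop_small_clusters(min_cluster_size))
        from .clustering import pairwise_nmi_matrix
        m = pairwise_nmi_matrix(parts, restrict_to_common=True)
        off = m[np.triu_indices(n_runs, k=1)] if n_runs > 1 else np.array([1.0])
        rows.append({
            "p_e": p_e,
            "mean_clusters": float(np.mean(ks)),
            "pct_isolated": 100.0 * net.isolation_fraction,
            "mean_nmi": float(off.mean()),
            "nmi_cv": float(off.std() / off.mean()) if off.mean() else 0.0,
        })
    return pd.DataFrame(rows)
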