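"""Template-based classification of novel summary nodes.

Each test summary node is compared, by the combined similarity
``S2 = S_ICI * S_SPEC``, against every training summary node of every
click-type template.  The pooled set of test-to-training scores is
pruned at ``p_e`` (default 0.90 — looser than training, so poor-quality
test nodes can still find a match); the per-template score is the mean
of that template's surviving similarities (0 when none survive).  The
node is assigned to the arg-max template and the winning score is kept
as a *certainty*; below the certainty threshold (default 0.3) the node
is labeled "Unknown".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phase1 import SummaryNode
from .phase2 import ClickTypeTemplate
from .similarity import (combined_similarity, ici_similarity,
                         normalize_spectra, retained_edge_count,
                         spectral_similarity)

UNKNOWN = "Unknown"

__all__ = [
    "UNKNOWN", "Classification", "classify_node", "classify_nodes",
    "evaluate_confusion", "unknown_disagreement_share", "confusion_stats",
    "certainty_accuracy_curve",
]


@dataclass
class Classification:
    """One classified node: winning label, certainty, per-template scores."""

    node_ref: str
    assigned_label: str
    certainty: float
    scores: dict


class _TrainingPool:
    """Stacked, pre-normalized training nodes from a template set."""

    def __init__(self, templates: list[ClickTypeTemplate]):
        if not templates:
            raise ValueError("no templates supplied")
        self.labels = [t.label for t in templates]
        spectra, icis, owner = [], [], []
        for k, t in enumerate(templates):
            for m in t.members:
                if m.modal_ici is None:
                    continue
                spectra.append(m.mean_spectrum)
                icis.append(m.modal_ici)
                owner.append(k)
        norm, valid = normalize_spectra(np.vstack(spectra))
        self.spectra = norm[valid]
        self.icis = np.asarray(icis, dtype=float)[valid]
        self.owner = np.asarray(owner, dtype=int)[valid]


def _score_node(node: SummaryNode, pool: _TrainingPool, p_e: float
                ) -> dict:
    norm = normalize_spectra(node.mean_spectrum[None, :])[0][0]
    s_spec = spectral_similarity(norm[None, :], pool.spectra)[0]
    s_ici = ici_similarity(node.modal_ici, pool.icis)
    s2 = combined_similarity(s_spec, s_ici)
    finite = np.isfinite(s2)
    idx = np.flatnonzero(finite)
    keep_n = retained_edge_count(idx.size, p_e)
    # prune the pooled test-to-training edge set: one percentile computation
    order = idx[np.lexsort((idx, s2[idx]))]
    survivors = order[idx.size - keep_n:] if keep_n > 0 else order[:0]
    scores = {}
    for k, lab in enumerate(pool.labels):
        mine = survivors[pool.owner[survivors] == k]
        scores[lab] = float(s2[mine].mean()) if mine.size else 0.0
    return scores


def classify_node(node: SummaryNode, templates: list[ClickTypeTemplate],
                  p_e: float = 0.90, threshold: float = 0.3,
                  node_ref: str | None = None) -> Classification:
    """Assign one summary node to a click-type template (or "Unknown").

    Ties on the winning score are broken by template label order (so
    permuting the input template list never changes the outcome).
    """
    pool = _TrainingPool(templates)
    return _classify_with_pool(node, pool, p_e, threshold, node_ref)


def _classify_with_pool(node, pool, p_e, threshold, node_ref=None) -> Classification:
    if node.modal_ici is None:
        raise ValueError("test node has no modal ICI; cannot classify")
    scores = _score_node(node, pool, p_e)
    winner = max(sorted(scores), key=lambda lab: scores[lab])
    certainty = scores[winner]
    label = winner if certainty >= threshold else UNKNOWN
    ref = node_ref if node_ref is not None else f"{node.site_id}@{node.bin_start:.0f}"
    return Classification(node_ref=ref, assigned_label=label,
                          certainty=certainty, scores=scores)


def classify_nodes(nodes: list[SummaryNode], templates: list[ClickTypeTemplate],
                   p_e: float = 0.90, threshold: float = 0.3) -> list[Classification]:
    """Classify a batch of summary nodes against one template set."""
    pool = _TrainingPool(templates)
    return [_classify_with_pool(n, pool, p_e, threshold) for n in nodes]


# ---------------------------------------------------------------------------
# evaluation against reference labels

def evaluate_confusion(auto_labels, ref_labels, labels: list[str] | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Confusion matrix (rows = automatic, columns = reference) and summary stats.

    See :func:`confusion_stats` for the statistics reported.
    """
    auto_labels = list(auto_labels)
    ref_labels = list(ref_labels)
    if len(auto_labels) != len(ref_labels):
        raise ValueError("label vectors must have equal length")
    if labels is None:
        named = sorted(set(auto_labels) | set(ref_labels) - {UNKNOWN})
        named = [l for l in named if l != UNKNOWN]
        labels = named + [UNKNOWN]
    matrix = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for a, r in zip(auto_labels, ref_labels):
        matrix.loc[a, r] += 1
    return matrix, confusion_stats(matrix)


def unknown_disagreement_share(matrix: pd.DataFrame) -> float:
    """Share of off-diagonal disagreements where the automatic label was a
    named type but the reference label was Unknown."""
    vals = matrix.to_numpy(dtype=float)
    off_total = vals.sum() - np.trace(vals)
    if off_total == 0:
        return 0.0
    unk_col = matrix.columns.get_loc(UNKNOWN)
    auto_named = sum(
        vals[i, unk_col] for i, lab in enumerate(matrix.index) if lab != UNKNOWN
    )
    return float(auto_named / off_total)


def confusion_stats(matrix: pd.DataFrame) -> dict:
    """Agreement statistics under both evaluation conventions.

    * ``agreement`` — diagonal fraction, counting Unknown-Unknown cells
      as agreement (the convention behind the headline
      unknown-disagreement share);
    * ``agreement_strict`` — nodes labeled Unknown by either method
      count as mismatches;
    * ``unknown_disagreement_share`` — of the off-diagonal mismatches,
      the fraction where the automatic classifier assigned a named type
      while the reference was Unknown.
    """
    vals = matrix.to_numpy(dtype=float)
    total = vals.sum()
    diag = np.trace(vals)
    unk_i = matrix.index.get_loc(UNKNOWN) if UNKNOWN in matrix.index else None
    strict_diag = diag - (vals[unk_i, unk_i] if unk_i is not None else 0.0)
    return {
        "n": int(total),
        "agreement": float(diag / total) if total else 0.0,
        "agreement_strict": float(strict_diag / total) if total else 0.0,
        "n_mismatched": int(total - diag),
        "unknown_disagreement_share": unknown_disagreement_share(matrix),
    }


def certainty_accuracy_curve(classifications: list[Classification], ref_labels,
                             score_bins=None) -> pd.DataFrame:
    """Agreement rate as a function of classification certainty.

    Bins are inclusive on the left, exclusive on the right (the last bin
    includes its right edge so certainty 1.0 is counted).  Empty input
    yields an empty table.
    """
    if score_bins is None:
        score_bins = np.round(np.arange(0.0, 1.01, 0.1), 10)
    score_bins = np.asarray(score_bins, dtype=float)
    rows = []
    certs = np.array([c.certainty for c in classifications])
    agree = np.array([c.assigned_label == r for c, r in zip(classifications, ref_labels)])
    for lo, hi in zip(score_bins[:-1], score_bins[1:]):
        last = hi == score_bins[-1]
        sel = (certs >= lo) & ((certs <= hi) if last else (certs < hi))
        rows.append({
            "bin_left": lo,
            "bin_right": hi,
            "n": int(sel.sum()),
            "pct_agreement": 100.0 * float(agree[sel].mean()) if sel.any() else np.nan,
        })
    return pd.DataFrame(rows)
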