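"""Template classification, certainty scoring and confusion evaluation."""

import copy
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from echotype.classify import (UNKNOWN, certainty_accuracy_curve, classify_node,
                               classify_nodes, confusion_stats,
                               evaluate_confusion, unknown_disagreement_share)
from echotype.io import read_confusion_matrix
from echotype.phase2 import Phase2Config, discover_types
from echotype.similarity import (combined_similarity, ici_similarity,
                                 normalize_spectra, retained_edge_count,
                                 spectral_similarity)
from echotype.simulate import (SEVEN_TYPE_PRESET, THREE_TYPE_PRESET,
                               synth_summary_nodes)

DATA = Path(__file__).parent / "data"
BY_LABEL = {s.label: s for s in SEVEN_TYPE_PRESET}


@pytest.fixture(scope="module")
def trained_three():
    """Templates trained on fabricated three-type summary nodes."""
    nodes, labels = synth_summary_nodes(THREE_TYPE_PRESET, 80,
                                        sites=("S1", "S2"), rng_seed=31)
    res = discover_types(nodes, Phase2Config(rng_seed=7))
    # template label -> planted type, via member majority
    mapping = {}
    for t in res.templates:
        idx = [nodes.index(m) for m in t.members]
        mapping[t.label] = Counter(labels[i] for i in idx).most_common(1)[0][0]
    return res.templates, mapping


class TestClassifyNode:
    def test_identical_to_one_template_scores_one(self, trained_three):
        templates, _ = trained_three
        # clone all members of one template to be identical to the probe
        probe = copy.deepcopy(templates[0].members[0])
        rigged = copy.deepcopy(templates)
        for m in rigged[0].members:
            m.mean_spectrum = probe.mean_spectrum.copy()
            m.modal_ici = probe.modal_ici
        c = classify_node(probe, rigged)
        assert c.assigned_label == rigged[0].label
        assert c.certainty == pytest.approx(1.0, abs=1e-9)

    def test_poor_match_goes_unknown(self, trained_three, rng):
        templates, _ = trained_three
        probe = copy.deepcopy(templates[0].members[0])
        # sawtooth spectrum: dissimilar in shape to every template
        probe.mean_spectrum = np.where(np.arange(121) % 2 == 0, 100.0, 80.0) \
            + rng.normal(0, 0.1, 121)
        probe.modal_ici = 0.495
        c = classify_node(probe, templates)
        assert c.certainty < 0.3
        assert c.assigned_label == UNKNOWN

    def test_scores_match_prune_then_mean_oracle(self, trained_three):
        templates, _ = trained_three
        probe = templates[1].members[3]
        c = classify_node(probe, templates, p_e=0.90)
        # brute-force oracle over the pooled test-to-training edge set
        norm_probe = normalize_spectra(probe.mean_spectrum[None, :])[0][0]
        sims, owners = [], []
        for t in templates:
            for m in t.members:
                norm_m = normalize_spectra(m.mean_spectrum[None, :])[0][0]
                s = spectral_similarity(norm_probe[None, :], norm_m[None, :])[0, 0]
                sims.append(s * ici_similarity(probe.modal_ici, m.modal_ici))
                owners.append(t.label)
        sims = np.array(sims)
        keep = retained_edge_count(len(sims), 0.90)
        cut = np.sort(sims)[len(sims) - keep]
        for lab in {t.label for t in templates}:
            surv = sims[(sims >= cut) & (np.array(owners) == lab)]
            expected = float(surv.mean()) if surv.size else 0.0
            assert c.scores[lab] == pytest.approx(expected, abs=1e-9)

    def test_template_order_irrelevant(self, trained_three):
        templates, _ = trained_three
        probe = templates[0].members[0]
        a = classify_node(probe, templates)
        b = classify_node(probe, templates[::-1])
        assert a.assigned_label == b.assigned_label
        assert a.certainty == pytest.approx(b.certainty, abs=1e-12)

    def test_lower_threshold_never_unknowns_a_typed_node(self, trained_three):
        templates, _ = trained_three
        probe = templates[0].members[0]
        hi = classify_node(probe, templates, threshold=0.3)
        lo = classify_node(probe, templates, threshold=0.1)
        if hi.assigned_label != UNKNOWN:
            assert lo.assigned_label == hi.assigned_label

    def test_no_templates_rejected(self, trained_three):
        with pytest.raises(ValueError):
            classify_node(trained_three[0][0].members[0], [])

    def test_recall_and_unknown_rate_on_fresh_nodes(self, trained_three):
        templates, mapping = trained_three
        fresh, fresh_labels = synth_summary_nodes(THREE_TYPE_PRESET, 50,
                                                  sites=("S3",), rng_seed=99)
        results = classify_nodes(fresh, templates, p_e=0.90, threshold=0.3)
        assert all(0.0 <= c.certainty <= 1.0 for c in results)
        unknown_rate = np.mean([c.assigned_label == UNKNOWN for c in results])
        assert unknown_rate <= 0.1
        for planted in set(fresh_labels):
            idx = [i for i, l in enumerate(fresh_labels) if l == planted]
            hits = [mapping.get(results[i].assigned_label) == planted for i in idx]
            assert np.mean(hits) >= 0.9


class TestConfusion:
    def test_identical_labels_full_agreement(self):
        labs = list("ABCABCAB")
        m, stats = evaluate_confusion(labs, labs)
        assert stats["agreement"] == 1.0 and stats["n_mismatched"] == 0
        assert unknown_disagreement_share(m) == 0.0

    def test_matrix_matches_pair_counting_oracle(self, rng):
        labels = list("ABCDEFG") + [UNKNOWN]
        auto = [labels[i] for i in rng.integers(0, 8, 300)]
        ref = [labels[i] for i in rng.integers(0, 8, 300)]
        m, _ = evaluate_confusion(auto, ref)
        assert int(m.to_numpy().sum()) == 300
        for a in labels[:3]:
            for r in labels[:3]:
                direct = sum(1 for x, y in zip(auto, ref) if x == a and y == r)
                assert m.loc[a, r] == direct

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_confusion(["A"], ["A", "B"])

    def test_field_confusion_counts_reproduce_unknown_share(self):
        """A published 1000-node evaluation: 47% of the off-diagonal
        disagreements are auto-typed nodes the reference left Unknown."""
        m = read_confusion_matrix(DATA / "table5_confusion.tsv")
        stats = confusion_stats(m)
        assert stats["n"] == 1000 and stats["n_mismatched"] == 158
        assert round(100 * stats["unknown_disagreement_share"]) == 47
        # strict convention counts Unknown-Unknown agreements as mismatches
        assert stats["agreement_strict"] < stats["agreement"]


class TestCertaintyCurve:
    def test_all_correct_is_flat_100(self):
        cls = [type("C", (), {"certainty": c, "assigned_label": "A"})()
               for c in [0.15, 0.45, 0.75, 0.95, 1.0]]
        df = certainty_accuracy_curve(cls, ["A"] * 5)
        occupied = df[df["n"] > 0]
        assert (occupied["pct_agreement"] == 100.0).all()
        assert df["n"].sum() == 5  # certainty 1.0 falls in the last bin

    def test_bin_counts_match_histogram_oracle(self, rng):
        certs = rng.uniform(0, 1, 200)
        cls = [type("C", (), {"certainty": c, "assigned_label": "A"})()
               for c in certs]
        df = certainty_accuracy_curve(cls, ["A"] * 200)
        oracle, _ = np.histogram(certs, bins=np.round(np.arange(0, 1.01, 0.1), 10))
        np.testing.assert_array_equal(df["n"].to_numpy(), oracle)

    def test_agreement_rises_with_certainty_on_noisy_labels(self, rng):
        # planted: probability of agreement equals the certainty score
        certs = rng.uniform(0, 1, 2000)
        agree = rng.uniform(0, 1, 2000) < certs
        cls = [type("C", (), {"certainty": c, "assigned_label": "A" if a else "B"})()
               for c, a in zip(certs, agree)]
        df = certainty_accuracy_curve(cls, ["A"] * 2000)
        vals = df["pct_agreement"].to_numpy()
        assert vals[-1] > vals[0]
        assert np.polyfit(np.arange(len(vals)), vals, 1)[0] > 0

    def test_empty_input_gives_empty_table(self):
        df = certainty_accuracy_curve([], [])
        assert df["n"].sum() == 0
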