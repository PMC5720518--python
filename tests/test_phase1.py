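"""Binning, encounters, ICI statistics and within-bin clustering."""

import numpy as np
import pytest

from echotype.io import DetectionTable
from echotype.phase1 import (ICI_BIN_EDGES, ICIDistribution, TimeBin,
                             assemble_bins, cluster_bin, compute_encounters,
                             ici_distribution, modal_ici, summarize)
from echotype.simulate import (DEFAULT_GRID_KHZ, SEVEN_TYPE_PRESET,
                               SyntheticDatasetSpec, spectral_noise,
                               synth_detection_dataset, template_spectrum)

A, B, D, G = (s for s in SEVEN_TYPE_PRESET if s.label in "ABDG")


def make_table(times, spectra=None, site="S1", rng=None):
    times = np.asarray(times, dtype=float)
    n = len(times)
    if spectra is None:
        rng = rng or np.random.default_rng(0)
        spectra = template_spectrum(A)[None, :] + rng.normal(0, 2, (n, 121))
    return DetectionTable(
        times=times, spectra=spectra, frequencies_khz=DEFAULT_GRID_KHZ,
        peak_frequency_khz=DEFAULT_GRID_KHZ[np.argmax(spectra, axis=1)],
        received_level_dbpp=np.full(n, 130.0),
        envelope_duration_s=np.full(n, 1.5e-4),
        site_id=np.array([site] * n, dtype=object),
        deployment_id=np.array(["D1"] * n, dtype=object),
    )


class TestAssembleBins:
    def test_small_bin_dropped(self):
        table = make_table(np.linspace(10, 290, 99))
        assert assemble_bins(table) == []

    def test_oversized_bin_subsampled_to_cap(self):
        table = make_table(np.linspace(0.01, 299.9, 7200))
        bins = assemble_bins(table, rng_seed=3)
        assert len(bins) == 1 and bins[0].n_clicks == 5000
        assert np.all(np.diff(bins[0].times) >= 0)  # time order preserved

    def test_boundary_split_matches_histogram_oracle(self, rng):
        times = rng.uniform(100, 500, 350)  # spans the t=300 boundary
        table = make_table(np.sort(times))
        bins = assemble_bins(table, min_clicks=1)
        counts = {b.bin_start: b.n_clicks for b in bins}
        oracle, edges = np.histogram(times, bins=[0, 300, 600])
        assert counts == {0.0: oracle[0], 300.0: oracle[1]}
        assert all(np.all((b.times >= b.bin_start)
                          & (b.times < b.bin_start + 300)) for b in bins)

    def test_sites_never_mix(self, rng):
        t = np.sort(rng.uniform(0, 300, 150))
        ta, tb = make_table(t, site="S1"), make_table(t, site="S2")
        merged = DetectionTable.concatenate([ta, tb])
        bins = assemble_bins(merged)
        assert sorted(b.site_id for b in bins) == ["S1", "S2"]

    def test_subsampling_is_seeded(self):
        table = make_table(np.linspace(0.01, 299.9, 6000))
        b1 = assemble_bins(table, rng_seed=5)[0]
        b2 = assemble_bins(table, rng_seed=5)[0]
        np.testing.assert_array_equal(b1.times, b2.times)


class TestEncounters:
    def test_long_gap_splits(self):
        times = np.concatenate([np.arange(0, 600, 5), np.arange(2400, 2700, 5)])
        enc = compute_encounters(times)
        assert len(enc) == 2
        assert enc[0].duration_min == pytest.approx((595 - 0) / 60)

    def test_exact_gap_splits(self):
        assert len(compute_encounters(np.array([0.0, 900.0]))) == 2
        assert len(compute_encounters(np.array([0.0, 899.9]))) == 1

    def test_matches_bruteforce_gap_scan(self, rng):
        times = np.sort(rng.uniform(0, 86400, 500))
        enc = compute_encounters(times)
        # brute-force scan
        count, n_in = 1, 1
        sizes = []
        for d in np.diff(times):
            if d >= 900:
                sizes.append(n_in)
                count += 1
                n_in = 1
            else:
                n_in += 1
        sizes.append(n_in)
        assert len(enc) == count
        assert [e.n_clicks for e in enc] == sizes

    def test_empty_stream(self):
        assert compute_encounters(np.array([])) == []


class TestICIDistribution:
    def test_metronomic_train(self):
        dist = ici_distribution(np.arange(50) * 0.155)
        assert dist.counts.sum() == 49
        center = dist.bin_centers[np.argmax(dist.counts)]
        assert center == pytest.approx(0.155)
        assert dist.modal() == pytest.approx(0.155)

    def test_out_of_range_excluded(self):
        dist = ici_distribution(np.arange(10) * 0.7)
        assert dist.counts.sum() == 0
        with pytest.raises(ValueError):
            dist.modal()

    def test_interleaved_trains_saturate_low_bins(self):
        t1 = np.arange(0, 60, 0.155)
        t2 = t1 + 0.07
        dist = ici_distribution(np.sort(np.concatenate([t1, t2])))
        # merged stream alternates 0.07 / 0.085 gaps
        top = dist.bin_centers[np.argsort(dist.counts)[-2:]]
        assert set(np.round(top, 3)) == {0.075, 0.085}

    def test_single_click_is_empty(self):
        assert ici_distribution(np.array([1.0])).counts.sum() == 0


class TestModalICI:
    @staticmethod
    def dist(counts):
        return ICIDistribution(bin_edges=ICI_BIN_EDGES,
                               counts=np.asarray(counts, dtype=int))

    def test_unimodal_argmax(self):
        counts = np.zeros(49, dtype=int)
        counts[11] = 30  # bin [0.12, 0.13) -> center 0.125
        counts[12] = 10
        assert modal_ici(self.dist(counts)) == pytest.approx(0.125)

    def test_saturation_uses_first_local_peak(self):
        counts = np.concatenate([[50, 40, 30, 20], np.zeros(45)]).astype(int)
        counts[5] = 25  # secondary bump at center 0.065
        counts[4] = 10
        counts[6] = 10
        assert modal_ici(self.dist(counts)) == pytest.approx(0.065)

    def test_monotone_decay_without_bump_falls_back_to_argmax(self):
        counts = np.concatenate([np.arange(49, 0, -1)]).astype(int)
        assert modal_ici(self.dist(counts)) == pytest.approx(0.015)

    def test_tie_takes_lower_bin(self):
        counts = np.zeros(49, dtype=int)
        counts[10] = counts[20] = 7
        assert modal_ici(self.dist(counts)) == pytest.approx(ICI_BIN_EDGES[10] + 0.005)


def planted_bin(specs_and_counts, rng, ici_specs=None):
    """One TimeBin with interleaved trains from the given type specs."""
    times, spectra = [], []
    for spec, n in specs_and_counts:
        tt = np.arange(n) * spec.modal_ici_s + rng.uniform(0, 1)
        base = template_spectrum(spec)
        times.append(tt)
        spectra.append(base[None, :] + spectral_noise(spec, rng, (n, 121))
                       + rng.normal(0, spec.level_sd_db, (n, 1)))
    times = np.concatenate(times)
    spectra = np.vstack(spectra)
    order = np.argsort(times)
    return TimeBin(bin_start=0.0, duration_s=300.0, times=times[order],
                   spectra=spectra[order], frequencies_khz=DEFAULT_GRID_KHZ,
                   site_id="S1", deployment_id="D1")


class TestClusterBin:
    def test_single_type_bin_gives_one_node(self, rng):
        b = planted_bin([(A, 300)], rng)
        nodes = cluster_bin(b, rng_seed=1)
        assert len(nodes) == 1
        node = nodes[0]
        assert node.n_clicks >= 250
        rms = np.sqrt(np.mean((node.mean_spectrum - template_spectrum(A)
                               - np.mean(node.mean_spectrum - template_spectrum(A))) ** 2))
        assert rms < 1.0
        assert node.modal_ici == pytest.approx(0.155)

    def test_two_separated_types_give_two_nodes(self, rng):
        # two types of comparable within-type coherence interleaved in one bin
        b = planted_bin([(A, 150), (D, 150)], rng)
        nodes = cluster_bin(b, rng_seed=1)
        assert len(nodes) == 2
        peaks = sorted(n.peak_frequency_khz for n in nodes)
        assert abs(peaks[0] - A.peak_khz) < 2 and abs(peaks[1] - D.peak_khz) < 2
        icis = sorted(n.modal_ici for n in nodes)
        assert icis[0] == pytest.approx(D.modal_ici_s) \
            and icis[1] == pytest.approx(A.modal_ici_s)

    def test_outliers_do_not_form_nodes(self, rng):
        b = planted_bin([(A, 120)], rng)
        # 60 incoherent outliers: independent rough spectra
        junk = rng.normal(100, 8, (60, 121))
        b = TimeBin(bin_start=0.0, duration_s=300.0,
                    times=np.concatenate([b.times, rng.uniform(0, 300, 60)]),
                    spectra=np.vstack([b.spectra, junk]),
                    frequencies_khz=DEFAULT_GRID_KHZ, site_id="S1",
                    deployment_id="D1")
        nodes = cluster_bin(b, rng_seed=1)
        assert len(nodes) == 1 and nodes[0].n_clicks <= 130

    def test_all_subcritical_gives_nothing(self, rng):
        b = planted_bin([(A, 50)], rng)
        assert cluster_bin(b, rng_seed=0) == []


@pytest.fixture(scope="module")
def small_dataset():
    spec = SyntheticDatasetSpec(bins_per_type_per_site=2, sites=("S1", "S2"),
                                mixture_fraction=0.0, rng_seed=21)
    return synth_detection_dataset(spec)


class TestSummarize:
    def test_nodes_per_bin_in_sanity_band(self, small_dataset, quiet):
        table, _ = small_dataset
        nodes = summarize(table, rng_seed=4)
        n_bins = len(assemble_bins(table))
        assert n_bins == 28
        assert 1.0 <= len(nodes) / n_bins <= 1.2

    def test_invariant_to_click_order(self, small_dataset, quiet, rng):
        table, _ = small_dataset
        shuffled = table.select(rng.permutation(len(table)))
        a = summarize(table, rng_seed=4)
        b = summarize(shuffled, rng_seed=4)
        assert len(a) == len(b)
        for na, nb in zip(a, b):
            assert (na.site_id, na.bin_start, na.n_clicks) == \
                (nb.site_id, nb.bin_start, nb.n_clicks)
            np.testing.assert_allclose(na.mean_spectrum, nb.mean_spectrum, atol=1e-9)

    def test_isolation_grows_with_pruning(self, small_dataset, quiet):
        from echotype.similarity import prune_network, spectral_similarity
        from echotype.similarity import normalize_spectra
        table, _ = small_dataset
        b = assemble_bins(table)[0]
        norm, valid = normalize_spectra(b.spectra)
        sim = spectral_similarity(norm[valid])
        prev = -1
        for p_e in [0.0, 0.5, 0.9, 0.95, 0.99]:
            iso = len(prune_network(sim, p_e).isolated_nodes)
            assert iso >= prev
            prev = iso
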