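"""Ground-truthed synthetic data at two levels of fidelity.

Two generation paths exercise different parts of the pipeline:

* **audio level** — broadband tone-burst clicks (Gaussian-enveloped
  cosines, optionally with secondary components) planted in Gaussian
  background noise, plus snapping-shrimp-like false-positive transients
  (very short, energy concentrated above 70 kHz).  This path tests the
  detector end to end and is deliberately small-scale.
* **detection level** — click tables with spectra drawn directly from
  type templates plus noise, scaling to 10^4-10^5 clicks in seconds.
  This is the primary path for clustering and classification tests.

The seven-type preset mirrors the dominant delphinid click types
reported from long-term Gulf of Mexico monitoring: type-specific
spectral shapes with peaks and notches between 10 and 70 kHz, modal
inter-click intervals between 0.03 and 0.17 s, and strongly uneven
prevalence (two types together cover about two thirds of click-positive
bins).  All outputs are fully determined by the supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from scipy.ndimage import gaussian_filter1d

from .detection import AudioSegment
from .io import DetectionTable
from .phase1 import ICI_BIN_EDGES, ICIDistribution, SummaryNode, modal_ici

__all__ = [
    "DEFAULT_GRID_KHZ",
    "ClickTypeSpec",
    "SyntheticDatasetSpec",
    "template_spectrum",
    "spectral_noise",
    "synth_click_waveform",
    "synth_audio_bin",
    "synth_detection_dataset",
    "synth_summary_nodes",
    "SEVEN_TYPE_PRESET",
    "THREE_TYPE_PRESET",
    "TRAINING_BIN_COUNTS",
    "TRAINING_TOTAL_BINS",
    "training_set_shares",
]

#: Standard spectrum grid: 10-70 kHz at 500 Hz spacing (121 bins).
DEFAULT_GRID_KHZ = np.round(np.arange(10.0, 70.01, 0.5), 10)


@dataclass(frozen=True)
class ClickTypeSpec:
    """Generative parameters of one click type.

    The spectral template is a smooth dB shape over 10-70 kHz: a
    dominant Gaussian lobe at ``peak_khz`` (amplitude ``main_amp_db``
    above the floor, width ``bandwidth_khz``), optional secondary peaks
    and notches (frequency kHz, dB relative to the main lobe / notch
    depth, width), on a gently tilted baseline.  Click timing follows a
    renewal train at ``modal_ici_s`` with multiplicative jitter; received
    levels are normal in dB around ``level_mean_dbpp``.
    """

    label: str
    peak_khz: float
    bandwidth_khz: float
    modal_ici_s: float
    secondary_peaks: tuple = ()       # (khz, rel_db, sigma_khz)
    notches: tuple = ()               # (khz, depth_db, sigma_khz)
    main_amp_db: float = 25.0
    lobe_exponent: float = 2.0        # 2 = Gaussian lobe; >2 = flat top, steep band edges
    tilt_db_per_khz: float = -0.15
    ici_jitter_cv: float = 0.05
    level_mean_dbpp: float = 130.0
    level_sd_db: float = 4.0
    spectral_noise_db: float = 2.5
    spectral_noise_smooth_bins: float = 4.0  # frequency correlation scale
    bin_peak_jitter_khz: float = 0.3  # per-bin template peak wander
    bin_noise_db: float = 1.2         # per-bin propagation/noise conditions,
                                      # shared by all clicks of the bin's train
    bin_ici_jitter_cv: float = 0.05   # per-bin ICI scale wander

    def __post_init__(self):
        if self.bandwidth_khz <= 0:
            raise ValueError(f"{self.label}: bandwidth must be positive")
        if not 15.0 <= self.peak_khz <= 85.0:
            raise ValueError(f"{self.label}: peak frequency outside 15-85 kHz")
        if not 0.01 <= self.modal_ici_s < 0.5:
            raise ValueError(f"{self.label}: modal ICI outside [0.01, 0.5) s")


def spectral_noise(spec: ClickTypeSpec, rng: np.random.Generator,
                   shape: tuple, sigma_db: float | None = None) -> np.ndarray:
    """Within-type spectral variability: frequency-correlated dB noise.

    Propagation, orientation and interference perturb click spectra
    smoothly across frequency, so the noise is low-pass in the frequency
    axis (Gaussian kernel of ``spectral_noise_smooth_bins``) and scaled
    to ``spectral_noise_db`` per bin.
    """
    z = rng.normal(0.0, 1.0, shape)
    if spec.spectral_noise_smooth_bins > 0:
        z = gaussian_filter1d(z, spec.spectral_noise_smooth_bins, axis=-1)
        sd = z.std(axis=-1, keepdims=True)
        z = z / np.where(sd > 0, sd, 1.0)
    return (spec.spectral_noise_db if sigma_db is None else sigma_db) * z


def template_spectrum(spec: ClickTypeSpec, freqs_khz: np.ndarray = DEFAULT_GRID_KHZ,
                      peak_shift_khz: float = 0.0) -> np.ndarray:
    """Deterministic dB spectral template of a click type.

    ``peak_shift_khz`` translates the whole peak/notch structure, used
    for per-bin template wander.
    """
    f = np.asarray(freqs_khz, dtype=float)
    peak = spec.peak_khz + peak_shift_khz
    # lobes combine by envelope maximum so the dominant lobe keeps the argmax
    lobes = [spec.main_amp_db * np.exp(
        -0.5 * np.abs((f - peak) / spec.bandwidth_khz) ** spec.lobe_exponent)]
    for khz, rel_db, sig in spec.secondary_peaks:
        lobes.append((spec.main_amp_db + rel_db) * np.exp(
            -0.5 * ((f - (khz + peak_shift_khz)) / sig) ** 2))
    out = spec.tilt_db_per_khz * (f - peak) + np.maximum.reduce(lobes)
    for khz, depth_db, sig in spec.notches:
        out = out - depth_db * np.exp(-0.5 * ((f - (khz + peak_shift_khz)) / sig) ** 2)
    return out


# ---------------------------------------------------------------------------
# presets

#: Dominant click types as observed in two years of Gulf of Mexico
#: monitoring: (peak kHz, modal ICI s) pairs with the spectral structure
#: described for each type (narrow multi-peak structure for the
#: Risso's-like type B, low-frequency content for C, broadband G, ...).
SEVEN_TYPE_PRESET: tuple[ClickTypeSpec, ...] = (
    ClickTypeSpec("A", peak_khz=27.1, bandwidth_khz=5.5, modal_ici_s=0.155,
                  secondary_peaks=((12.0, -9.0, 1.0),)),
    ClickTypeSpec("B", peak_khz=33.2, bandwidth_khz=2.5, modal_ici_s=0.125,
                  secondary_peaks=((22.0, -4.0, 1.5), (26.0, -2.5, 1.5))),
    ClickTypeSpec("C", peak_khz=21.7, bandwidth_khz=5.0, modal_ici_s=0.165,
                  tilt_db_per_khz=-0.30),
    ClickTypeSpec("D", peak_khz=42.2, bandwidth_khz=7.0, modal_ici_s=0.035,
                  secondary_peaks=((12.0, -10.0, 1.2), (18.0, -8.0, 1.5))),
    ClickTypeSpec("E", peak_khz=32.3, bandwidth_khz=5.5, modal_ici_s=0.065,
                  tilt_db_per_khz=-0.22),
    ClickTypeSpec("F", peak_khz=30.3, bandwidth_khz=6.5, modal_ici_s=0.065,
                  secondary_peaks=((20.0, -5.0, 2.0), (16.0, -9.0, 1.5))),
    ClickTypeSpec("G", peak_khz=36.5, bandwidth_khz=11.0, modal_ici_s=0.035,
                  lobe_exponent=4.0, tilt_db_per_khz=0.0),
)

THREE_TYPE_PRESET: tuple[ClickTypeSpec, ...] = tuple(
    s for s in SEVEN_TYPE_PRESET if s.label in ("B", "E", "G"))

#: Click-positive training-bin counts per type (of 5,000 training bins),
#: used as realistic prevalence weights for large synthetic datasets.
TRAINING_BIN_COUNTS: dict[str, int] = {
    "A": 91, "B": 205, "C": 74, "D": 231, "E": 1118, "F": 2328, "G": 833,
}
TRAINING_TOTAL_BINS: int = 5000


def training_set_shares(counts: dict[str, int] | None = None,
                        total_bins: int | None = None) -> dict[str, float]:
    """Percentage of training bins per click type."""
    counts = TRAINING_BIN_COUNTS if counts is None else counts
    total = TRAINING_TOTAL_BINS if total_bins is None else total_bins
    return {lab: 100.0 * n / total for lab, n in counts.items()}


# ---------------------------------------------------------------------------
# audio-level synthesis

def synth_click_waveform(spec: ClickTypeSpec, rng: np.random.Generator,
                         sample_rate: float = 200e3,
                         calibration_db: float = 140.0,
                         level_dbpp: float | None = None
                         ) -> tuple[np.ndarray, float]:
    """One click as a sum of Gaussian-enveloped cosines.

    The main component sits at the type's peak frequency with envelope
    width set by its bandwidth (``sigma_t = 1 / (2 pi sigma_f)``);
    secondary spectral peaks contribute additional tone bursts at their
    relative amplitudes.  The waveform is scaled so its peak-to-peak
    level equals ``level_dbpp`` (drawn from the type's level
    distribution when not given) under the supplied calibration.

    Returns ``(waveform, level_dbpp)``; the click center sits at the
    middle sample.
    """
    sigma_t = 1.0 / (2.0 * np.pi * spec.bandwidth_khz * 1e3)
    half = min(int(np.ceil(6 * sigma_t * sample_rate)) + 20, 190)
    t = (np.arange(2 * half + 1) - half) / sample_rate
    wave = np.cos(2 * np.pi * spec.peak_khz * 1e3 * t + rng.uniform(0, 2 * np.pi)) \
        * np.exp(-0.5 * (t / sigma_t) ** 2)
    for khz, rel_db, sig_khz in spec.secondary_peaks:
        amp = 10.0 ** (rel_db / 20.0)
        sig_t = 1.0 / (2.0 * np.pi * sig_khz * 1e3)
        sig_t = min(sig_t, half / sample_rate / 4.0)
        wave = wave + amp * np.cos(2 * np.pi * khz * 1e3 * t + rng.uniform(0, 2 * np.pi)) \
            * np.exp(-0.5 * (t / sig_t) ** 2)
    if level_dbpp is None:
        level_dbpp = float(rng.normal(spec.level_mean_dbpp, spec.level_sd_db))
    pp = wave.max() - wave.min()
    target_pp = 10.0 ** ((level_dbpp - calibration_db) / 20.0)
    return wave * (target_pp / pp), level_dbpp


def _shrimp_transient(rng: np.random.Generator, sample_rate: float,
                      calibration_db: float) -> tuple[np.ndarray, float]:
    """Snapping-shrimp-like false positive: <50 us, energy above 70 kHz."""
    carrier_khz = float(np.clip(rng.normal(93.0, 2.0), 85.0, 97.0))
    sigma_t = 15e-6
    half = int(np.ceil(5 * sigma_t * sample_rate))
    t = (np.arange(2 * half + 1) - half) / sample_rate
    wave = np.cos(2 * np.pi * carrier_khz * 1e3 * t + rng.uniform(0, 2 * np.pi)) \
        * np.exp(-0.5 * (t / sigma_t) ** 2)
    level = float(rng.normal(126.0, 5.0))
    pp = wave.max() - wave.min()
    wave *= 10.0 ** ((level - calibration_db) / 20.0) / pp
    return wave, level


def _train_times(rng: np.random.Generator, ici: float, cv: float,
                 duration: float, margin: float, n_max: int | None = None
                 ) -> np.ndarray:
    """Click times of one jittered renewal train inside [margin, duration-margin]."""
    times = [margin + float(rng.uniform(0.0, ici))]
    while True:
        step = max(ici * (1.0 + cv * rng.standard_normal()), 0.005)
        nxt = times[-1] + step
        if nxt > duration - margin or (n_max is not None and len(times) >= n_max):
            break
        times.append(nxt)
    return np.asarray(times)


def synth_audio_bin(specs, duration_s: float = 300.0, *,
                    sample_rate: float = 200e3, calibration_db: float = 140.0,
                    noise_level_db: float = 80.0, shrimp_rate_hz: float = 0.0,
                    start_time: float = 0.0, rng: np.random.Generator
                    ) -> tuple[AudioSegment, pd.DataFrame]:
    """Synthesize one audio bin with known ground truth.

    Gaussian background noise at ``noise_level_db`` (broadband RMS, dB re
    1 uPa), one jittered click train per supplied type spec, and optional
    shrimp-like transients at ``shrimp_rate_hz``.  Returns the audio
    segment plus a truth table (time, label, level_dbpp), where each time
    marks the click's envelope center.
    """
    n = int(round(duration_s * sample_rate))
    sigma = 10.0 ** ((noise_level_db - calibration_db) / 20.0)
    samples = rng.normal(0.0, sigma, n)

    rows = []
    for spec in specs:
        for t in _train_times(rng, spec.modal_ici_s, spec.ici_jitter_cv,
                              duration_s, margin=0.01):
            wave, level = synth_click_waveform(spec, rng, sample_rate, calibration_db)
            c = int(round(t * sample_rate))
            half = len(wave) // 2
            lo, hi = c - half, c - half + len(wave)
            if lo < 0 or hi > n:
                continue
            samples[lo:hi] += wave
            rows.append({"time": start_time + t, "label": spec.label,
                         "level_dbpp": level})
    if shrimp_rate_hz > 0:
        for t in np.sort(rng.uniform(0.01, duration_s - 0.01,
                                     rng.poisson(shrimp_rate_hz * duration_s))):
            wave, level = _shrimp_transient(rng, sample_rate, calibration_db)
            c = int(round(t * sample_rate))
            half = len(wave) // 2
            samples[c - half:c - half + len(wave)] += wave
            rows.append({"time": start_time + t, "label": "FP",
                         "level_dbpp": level})
    truth = pd.DataFrame(rows, columns=["time", "label", "level_dbpp"])
    truth = truth.sort_values("time", ignore_index=True)
    audio = AudioSegment(samples=samples, sample_rate=sample_rate,
                         start_time=start_time, calibration_db=calibration_db)
    return audio, truth


# ---------------------------------------------------------------------------
# detection-level synthesis

@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Layout of a detection-level synthetic dataset.

    Each site receives ``bins_per_type_per_site`` 5-minute bins per click
    type, laid out sequentially; a ``mixture_fraction`` of bins carries a
    second, interleaved type.  A ``false_positive_fraction`` of each
    bin's clicks can be replaced by broadband impulsive false positives.
    """

    types: tuple = SEVEN_TYPE_PRESET
    sites: tuple = ("MC", "GC", "DT", "DC", "MP")
    bins_per_type_per_site: int = 12
    clicks_per_bin: tuple[int, int] = (150, 400)
    mixture_fraction: float = 0.05
    mixture_split: float = 0.5
    false_positive_fraction: float = 0.0
    bin_duration_s: float = 300.0
    start_time: float = 0.0
    rng_seed: int = 0
    frequencies_khz: np.ndarray = field(default_factory=lambda: DEFAULT_GRID_KHZ)


def _fp_spectrum(rng: np.random.Generator, freqs_khz: np.ndarray) -> np.ndarray:
    """Rough broadband false-positive spectrum: rising toward high frequency."""
    tilt = rng.uniform(0.1, 0.3)
    return tilt * (freqs_khz - freqs_khz[0]) + rng.normal(0.0, 4.0, len(freqs_khz))


def synth_detection_dataset(spec: SyntheticDatasetSpec | None = None
                            ) -> tuple[DetectionTable, pd.DataFrame]:
    """Generate click-level detection tables with per-click truth labels.

    Spectra are the type template (with per-bin peak wander) plus a
    per-click level offset and i.i.d. spectral noise; times follow
    jittered renewal trains at the type's modal ICI.  The returned truth
    frame is row-aligned with the detection table and carries
    ``time, site_id, bin_start, label``.
    """
    spec = spec or SyntheticDatasetSpec()
    rng = np.random.default_rng(spec.rng_seed)
    freqs = np.asarray(spec.frequencies_khz, dtype=float)
    by_label = {t.label: t for t in spec.types}

    tables, truth_rows = [], []
    for site in spec.sites:
        assignment = [t.label for t in spec.types for _ in range(spec.bins_per_type_per_site)]
        rng.shuffle(assignment)
        for slot, label in enumerate(assignment):
            bin_start = spec.start_time + slot * spec.bin_duration_s
            primary = by_label[label]
            trains = [(primary, 1.0)]
            if len(spec.types) > 1 and rng.uniform() < spec.mixture_fraction:
                others = [t for t in spec.types if t.label != label]
                second = others[int(rng.integers(len(others)))]
                trains = [(primary, 1.0 - spec.mixture_split),
                          (second, spec.mixture_split)]
            n_target = int(rng.integers(spec.clicks_per_bin[0], spec.clicks_per_bin[1] + 1))

            times, spectra, rls, labels = [], [], [], []
            for t_spec, frac in trains:
                n_train = max(2, int(round(frac * n_target)))
                ici = t_spec.modal_ici_s * (1.0 + t_spec.bin_ici_jitter_cv
                                            * rng.standard_normal())
                ici = float(np.clip(ici, 0.011, 0.49))
                tt = _train_times(rng, ici, t_spec.ici_jitter_cv,
                                  spec.bin_duration_s, margin=0.5, n_max=n_train)
                base = template_spectrum(
                    t_spec, freqs,
                    peak_shift_khz=float(rng.normal(0.0, t_spec.bin_peak_jitter_khz)))
                base = base + spectral_noise(t_spec, rng, (len(freqs),),
                                             sigma_db=t_spec.bin_noise_db)
                offs = rng.normal(0.0, t_spec.level_sd_db, len(tt))
                noise = spectral_noise(t_spec, rng, (len(tt), len(freqs)))
                times.append(bin_start + tt)
                spectra.append(base[None, :] + offs[:, None] + noise)
                rls.append(t_spec.level_mean_dbpp + offs)
                labels.extend([t_spec.label] * len(tt))

            times = np.concatenate(times)
            spectra = np.vstack(spectra)
            rls = np.concatenate(rls)
            labels = np.asarray(labels, dtype=object)

            if spec.false_positive_fraction > 0:
                n_fp = int(round(spec.false_positive_fraction * len(times)))
                if n_fp:
                    fp_t = bin_start + rng.uniform(0.5, spec.bin_duration_s - 0.5, n_fp)
                    fp_s = np.vstack([_fp_spectrum(rng, freqs) for _ in range(n_fp)])
                    times = np.concatenate([times, fp_t])
                    spectra = np.vstack([spectra, fp_s])
                    rls = np.concatenate([rls, rng.normal(126.0, 5.0, n_fp)])
                    labels = np.concatenate([labels, np.array(["FP"] * n_fp, dtype=object)])

            order = np.argsort(times, kind="stable")
            times, spectra, rls, labels = times[order], spectra[order], rls[order], labels[order]
            tables.append(DetectionTable(
                times=times,
                spectra=spectra,
                frequencies_khz=freqs,
                peak_frequency_khz=freqs[np.argmax(spectra, axis=1)],
                received_level_dbpp=rls,
                envelope_duration_s=np.exp(rng.normal(np.log(1.5e-4), 0.3, len(times))),
                site_id=np.array([site] * len(times), dtype=object),
                deployment_id=np.array([f"{site}01"] * len(times), dtype=object),
            ))
            for t, lab in zip(times, labels):
                truth_rows.append({"time": t, "site_id": site,
                                   "bin_start": bin_start, "label": lab})

    table = DetectionTable.concatenate(tables)
    truth = pd.DataFrame(truth_rows, columns=["time", "site_id", "bin_start", "label"])
    return table, truth


def synth_summary_nodes(types, n_per_type: int = 30, sites=("S1",),
                        rng_seed: int = 0, clicks_per_node: tuple[int, int] = (150, 400),
                        frequencies_khz: np.ndarray = DEFAULT_GRID_KHZ
                        ) -> tuple[list[SummaryNode], list[str]]:
    """Fabricate summary nodes directly from type specs (fast Phase 2 input).

    Emulates what Phase 1 would produce for single-type bins: the node's
    mean spectrum is the (per-bin wandered) template plus residual noise
    shrunk by the member count, and its ICI histogram comes from a
    simulated train at the type's modal ICI.  Returns ``(nodes, labels)``
    aligned by index; sites are assigned round-robin.
    """
    rng = np.random.default_rng(rng_seed)
    freqs = np.asarray(frequencies_khz, dtype=float)
    nodes, labels = [], []
    k = 0
    for t_spec in types:
        for _ in range(n_per_type):
            n_clicks = int(rng.integers(*clicks_per_node))
            base = template_spectrum(
                t_spec, freqs,
                peak_shift_khz=float(rng.normal(0.0, t_spec.bin_peak_jitter_khz)))
            mean_spec = base \
                + spectral_noise(t_spec, rng, (len(freqs),),
                                 sigma_db=t_spec.bin_noise_db) \
                + spectral_noise(t_spec, rng, (len(freqs),)) / np.sqrt(n_clicks)
            ici = t_spec.modal_ici_s * (1.0 + t_spec.bin_ici_jitter_cv
                                        * rng.standard_normal())
            icis = np.maximum(ici * (1.0 + t_spec.ici_jitter_cv
                                     * rng.standard_normal(n_clicks - 1)), 0.005)
            counts, _ = np.histogram(icis[(icis >= ICI_BIN_EDGES[0])
                                          & (icis < ICI_BIN_EDGES[-1])],
                                     bins=ICI_BIN_EDGES)
            dist = ICIDistribution(bin_edges=ICI_BIN_EDGES, counts=counts.astype(int))
            site = sites[k % len(sites)]
            nodes.append(SummaryNode(
                site_id=site, deployment_id=f"{site}01",
                bin_start=float(k * 300), n_clicks=n_clicks,
                frequencies_khz=freqs, mean_spectrum=mean_spec,
                ici=dist, modal_ici=modal_ici(dist) if counts.sum() else None,
            ))
            labels.append(t_spec.label)
            k += 1
    return nodes, labels
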