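"""File formats, configuration and containers tying the pipeline together.

All on-disk formats are plain text and versioned in their headers:

* detection tables — tab-separated, ISO 8601 timestamps, one
  comma-joined spectrum vector per row on a grid declared once in the
  header;
* summary-node files — JSON lines, first line is format metadata;
* click-type template bundles — a single JSON document;
* classification and confusion reports — tab-separated.

WAV audio is read/written with ``scipy.io.wavfile``; calibration and the
hydrophone transfer function travel in a JSON sidecar next to the WAV
(`<name>.wav.json`) because the format itself cannot carry them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .detection import AudioSegment, ClickDetection

DETECTIONS_FORMAT = "echotype-detections v1"
SUMMARY_FORMAT = "echotype-summary-nodes v1"
TEMPLATES_FORMAT = "echotype-templates v1"

__all__ = [
    "DetectionTable", "PipelineConfig",
    "read_audio", "write_audio",
    "write_detections", "read_detections",
    "write_summary_nodes", "read_summary_nodes",
    "write_template_bundle", "read_template_bundle",
    "write_classifications", "read_confusion_matrix", "write_confusion_matrix",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class DetectionTable:
    """Columnar store of detected clicks.

    ``times`` are seconds since the Unix epoch (UTC); spectra are dB
    levels on a fixed frequency grid shared by the whole table.
    """

    times: np.ndarray                 # (n,) float seconds
    spectra: np.ndarray               # (n, n_bins) dB
    frequencies_khz: np.ndarray       # (n_bins,)
    peak_frequency_khz: np.ndarray    # (n,)
    received_level_dbpp: np.ndarray   # (n,)
    envelope_duration_s: np.ndarray   # (n,)
    site_id: np.ndarray               # (n,) str
    deployment_id: np.ndarray         # (n,) str

    def __len__(self) -> int:
        return len(self.times)

    def select(self, idx) -> "DetectionTable":
        return DetectionTable(
            times=self.times[idx],
            spectra=self.spectra[idx],
            frequencies_khz=self.frequencies_khz,
            peak_frequency_khz=self.peak_frequency_khz[idx],
            received_level_dbpp=self.received_level_dbpp[idx],
            envelope_duration_s=self.envelope_duration_s[idx],
            site_id=self.site_id[idx],
            deployment_id=self.deployment_id[idx],
        )

    def sort_by_time(self) -> "DetectionTable":
        return self.select(np.argsort(self.times, kind="stable"))

    @classmethod
    def from_clicks(cls, clicks: list[ClickDetection], site_id: str = "S1",
                    deployment_id: str = "D1",
                    band_khz: tuple[float, float] = (10.0, 70.0)) -> "DetectionTable":
        """Build a table from detector output, truncating spectra to ``band_khz``."""
        if not clicks:
            raise ValueError("no clicks to tabulate")
        freqs = clicks[0].frequencies_khz
        sel = (freqs >= band_khz[0] - 1e-9) & (freqs <= band_khz[1] + 1e-9)
        n = len(clicks)
        return cls(
            times=np.array([c.start_time for c in clicks]),
            spectra=np.vstack([c.spectrum[sel] for c in clicks]),
            frequencies_khz=freqs[sel].copy(),
            peak_frequency_khz=np.array([c.peak_frequency_khz for c in clicks]),
            received_level_dbpp=np.array([c.received_level_dbpp for c in clicks]),
            envelope_duration_s=np.array([c.envelope_duration_s for c in clicks]),
            site_id=np.array([site_id] * n, dtype=object),
            deployment_id=np.array([deployment_id] * n, dtype=object),
        )

    @classmethod
    def concatenate(cls, tables: list["DetectionTable"]) -> "DetectionTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        f0 = tables[0].frequencies_khz
        for t in tables[1:]:
            if not np.allclose(t.frequencies_khz, f0):
                raise ValueError("detection tables use different frequency grids")
        return cls(
            times=np.concatenate([t.times for t in tables]),
            spectra=np.vstack([t.spectra for t in tables]),
            frequencies_khz=f0,
            peak_frequency_khz=np.concatenate([t.peak_frequency_khz for t in tables]),
            received_level_dbpp=np.concatenate([t.received_level_dbpp for t in tables]),
            envelope_duration_s=np.concatenate([t.envelope_duration_s for t in tables]),
            site_id=np.concatenate([t.site_id for t in tables]),
            deployment_id=np.concatenate([t.deployment_id for t in tables]),
        )


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline with its default value.

    Defaults are the operating point of the method: boundary threshold
    95 dB, QC window 15-85 kHz / >120 dB_pp, 5-minute bins with a
    100-click floor and 5,000-click cap, p_e = 0.95 for both clustering
    phases and 0.90 for classification, 1,000 summary nodes sampled per
    site, 20 consensus runs, 20-node minimum cluster size, and a 0.3
    certainty floor below which assignments become "Unknown".
    """

    bandpass_low_hz: float = 10e3
    bandpass_high_hz: float = 90e3
    boundary_threshold_db: float = 95.0
    min_peak_khz: float = 15.0
    max_peak_khz: float = 85.0
    min_received_level_dbpp: float = 120.0
    max_envelope_duration_s: float = 1e-3
    bin_duration_s: float = 300.0
    bin_min_clicks: int = 100
    bin_max_clicks: int = 5000
    p_e_phase1: float = 0.95
    phase1_min_cluster: int = 100
    p_e_phase2: float = 0.95
    phase2_min_cluster: int = 20
    nodes_per_site: int = 1000
    n_runs: int = 20
    max_iterations: int = 20
    p_e_classify: float = 0.90
    certainty_threshold: float = 0.3
    rng_seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# time helpers

def _iso(t: float) -> str:
    """Epoch seconds -> ISO 8601 UTC with microsecond precision."""
    return pd.Timestamp(round(t * 1e6), unit="us", tz="UTC").isoformat()


def _from_iso(s: str) -> float:
    return pd.Timestamp(s).timestamp()


# ---------------------------------------------------------------------------
# audio

def read_audio(path, calibration_db: float | None = None,
               start_time: float | None = None) -> AudioSegment:
    """Read single-channel WAV audio plus its calibration sidecar.

    The sidecar ``<path>.json`` must provide ``calibration_db`` and may
    provide ``start_time`` (ISO 8601) and ``transfer_function`` (list of
    ``[frequency_hz, db]`` pairs), unless ``calibration_db`` is given
    explicitly.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected single-channel audio, got shape {data.shape}")
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(float)

    tf = None
    t0 = 0.0 if start_time is None else start_time
    if calibration_db is None:
        sidecar = path.with_name(path.name + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"missing calibration sidecar {sidecar} for {path}; "
                "provide calibration_db explicitly or write the sidecar"
            )
        meta = json.loads(sidecar.read_text())
        calibration_db = float(meta["calibration_db"])
        if "start_time" in meta and start_time is None:
            t0 = _from_iso(meta["start_time"])
        if meta.get("transfer_function"):
            tf = np.asarray(meta["transfer_function"], dtype=float)
    return AudioSegment(samples=data, sample_rate=float(rate), start_time=t0,
                        calibration_db=calibration_db, transfer_function=tf)


def write_audio(path, segment: AudioSegment) -> None:
    """Write float32 WAV plus the calibration sidecar."""
    path = Path(path)
    wavfile.write(path, int(segment.sample_rate), segment.samples.astype(np.float32))
    meta = {
        "calibration_db": segment.calibration_db,
        "start_time": _iso(segment.start_time),
        "transfer_function": (
            None if segment.transfer_function is None
            else np.asarray(segment.transfer_function, dtype=float).tolist()
        ),
    }
    path.with_name(path.name + ".json").write_text(json.dumps(meta, indent=2) + "\n")


# ---------------------------------------------------------------------------
# detection tables

def _grid_header(freqs_khz: np.ndarray) -> str:
    step = freqs_khz[1] - freqs_khz[0] if len(freqs_khz) > 1 else 0.0
    return f"# spectrum_khz: start={freqs_khz[0]:.6f} stop={freqs_khz[-1]:.6f} step={step:.6f}"


def _parse_grid_header(line: str) -> np.ndarray:
    fields = dict(kv.split("=") for kv in line.split(":", 1)[1].split())
    start, stop, step = (float(fields[k]) for k in ("start", "stop", "step"))
    n = int(round((stop - start) / step)) + 1 if step else 1
    return start + step * np.arange(n)


def write_detections(path, table: DetectionTable) -> None:
    path = Path(path)
    cols = "detection_id\ttime\tsite_id\tdeployment_id\tpeak_frequency_khz\treceived_level_dbpp\tenvelope_duration_s\tspectrum"
    with open(path, "w") as fh:
        fh.write(f"# {DETECTIONS_FORMAT}\n")
        fh.write(_grid_header(table.frequencies_khz) + "\n")
        fh.write(cols + "\n")
        for k in range(len(table)):
            spec = ",".join(f"{v:.4f}" for v in table.spectra[k])
            fh.write(
                f"{k}\t{_iso(table.times[k])}\t{table.site_id[k]}\t{table.deployment_id[k]}"
                f"\t{table.peak_frequency_khz[k]:.4f}\t{table.received_level_dbpp[k]:.4f}"
                f"\t{table.envelope_duration_s[k]:.6e}\t{spec}\n"
            )


def read_detections(path) -> DetectionTable:
    path = Path(path)
    with open(path) as fh:
        fmt = fh.readline().strip().lstrip("# ")
        if fmt != DETECTIONS_FORMAT:
            raise ValueError(f"{path}: unrecognized format header {fmt!r}")
        freqs = _parse_grid_header(fh.readline().strip().lstrip("# "))
        df = pd.read_csv(fh, sep="\t")
    spectra = np.vstack([
        np.fromstring(s, sep=",") for s in df["spectrum"]
    ]) if len(df) else np.empty((0, len(freqs)))
    return DetectionTable(
        times=np.array([_from_iso(s) for s in df["time"]]),
        spectra=spectra,
        frequencies_khz=freqs,
        peak_frequency_khz=df["peak_frequency_khz"].to_numpy(float),
        received_level_dbpp=df["received_level_dbpp"].to_numpy(float),
        envelope_duration_s=df["envelope_duration_s"].to_numpy(float),
        site_id=df["site_id"].astype(str).to_numpy(dtype=object),
        deployment_id=df["deployment_id"].astype(str).to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# summary nodes (JSON lines)

def _node_to_obj(node) -> dict:
    return {
        "site_id": node.site_id,
        "deployment_id": node.deployment_id,
        "bin_start": _iso(node.bin_start),
        "n_clicks": int(node.n_clicks),
        "mean_spectrum": [round(float(v), 4) for v in node.mean_spectrum],
        "ici_counts": [int(c) for c in node.ici.counts],
        "modal_ici": None if node.modal_ici is None else round(float(node.modal_ici), 4),
    }


def write_summary_nodes(path, nodes, frequencies_khz: np.ndarray) -> None:
    with open(Path(path), "w") as fh:
        fh.write(json.dumps({
            "format": SUMMARY_FORMAT,
            "frequencies_khz": [round(float(f), 4) for f in frequencies_khz],
        }) + "\n")
        for node in nodes:
            fh.write(json.dumps(_node_to_obj(node)) + "\n")


def read_summary_nodes(path):
    from .phase1 import SummaryNode, ICIDistribution, ICI_BIN_EDGES

    with open(Path(path)) as fh:
        meta = json.loads(fh.readline())
        if meta.get("format") != SUMMARY_FORMAT:
            raise ValueError(f"{path}: unrecognized summary-node format")
        freqs = np.asarray(meta["frequencies_khz"], dtype=float)
        nodes = []
        for line in fh:
            obj = json.loads(line)
            counts = np.asarray(obj["ici_counts"], dtype=int)
            nodes.append(SummaryNode(
                site_id=obj["site_id"],
                deployment_id=obj.get("deployment_id", ""),
                bin_start=_from_iso(obj["bin_start"]),
                n_clicks=obj["n_clicks"],
                frequencies_khz=freqs,
                mean_spectrum=np.asarray(obj["mean_spectrum"], dtype=float),
                ici=ICIDistribution(bin_edges=ICI_BIN_EDGES, counts=counts),
                modal_ici=obj["modal_ici"],
            ))
    return nodes, freqs


# ---------------------------------------------------------------------------
# template bundles

def write_template_bundle(path, templates, frequencies_khz: np.ndarray,
                          config: PipelineConfig | None = None,
                          diagnostics: dict | None = None) -> None:
    """Write discovered click-type templates as a single JSON document."""
    doc = {
        "format": TEMPLATES_FORMAT,
        "frequencies_khz": [round(float(f), 4) for f in frequencies_khz],
        "config": asdict(config) if config is not None else None,
        "diagnostics": diagnostics,
        "templates": [],
    }
    for t in templates:
        doc["templates"].append({
            "label": t.label,
            "cluster_size": int(t.cluster_size),
            "mean_spectrum": [round(float(v), 6) for v in t.mean_spectrum],
            "p25_spectrum": [round(float(v), 6) for v in t.p25_spectrum],
            "p75_spectrum": [round(float(v), 6) for v in t.p75_spectrum],
            "ici_counts": [int(c) for c in t.ici_counts],
            "modal_ici": round(float(t.modal_ici), 4) if t.modal_ici is not None else None,
            "peak_frequency_mean_khz": round(float(t.peak_frequency_mean_khz), 4),
            "peak_frequency_cv": round(float(t.peak_frequency_cv), 4),
            "modal_ici_mean_s": round(float(t.modal_ici_mean_s), 4),
            "modal_ici_cv": round(float(t.modal_ici_cv), 4),
            "members": [_node_to_obj(n) for n in t.members],
        })
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_template_bundle(path):
    from .phase1 import SummaryNode, ICIDistribution, ICI_BIN_EDGES
    from .phase2 import ClickTypeTemplate

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != TEMPLATES_FORMAT:
        raise ValueError(f"{path}: unrecognized template-bundle format")
    freqs = np.asarray(doc["frequencies_khz"], dtype=float)
    templates = []
    for td in doc["templates"]:
        members = []
        for obj in td["members"]:
            counts = np.asarray(obj["ici_counts"], dtype=int)
            members.append(SummaryNode(
                site_id=obj["site_id"],
                deployment_id=obj.get("deployment_id", ""),
                bin_start=_from_iso(obj["bin_start"]),
                n_clicks=obj["n_clicks"],
                frequencies_khz=freqs,
                mean_spectrum=np.asarray(obj["mean_spectrum"], dtype=float),
                ici=ICIDistribution(bin_edges=ICI_BIN_EDGES, counts=counts),
                modal_ici=obj["modal_ici"],
            ))
        templates.append(ClickTypeTemplate(
            label=td["label"],
            members=members,
            frequencies_khz=freqs,
            mean_spectrum=np.asarray(td["mean_spectrum"], dtype=float),
            p25_spectrum=np.asarray(td["p25_spectrum"], dtype=float),
            p75_spectrum=np.asarray(td["p75_spectrum"], dtype=float),
            ici_counts=np.asarray(td["ici_counts"], dtype=int),
            modal_ici=td["modal_ici"],
            peak_frequency_mean_khz=td["peak_frequency_mean_khz"],
            peak_frequency_cv=td["peak_frequency_cv"],
            modal_ici_mean_s=td["modal_ici_mean_s"],
            modal_ici_cv=td["modal_ici_cv"],
        ))
    return templates, freqs, doc.get("config"), doc.get("diagnostics")


# ---------------------------------------------------------------------------
# classification / evaluation reports

def write_classifications(path, classifications) -> None:
    labels = sorted({lab for c in classifications for lab in c.scores})
    with open(Path(path), "w") as fh:
        fh.write("node_ref\tassigned_label\tcertainty\t"
                 + "\t".join(f"score_{l}" for l in labels) + "\n")
        for c in classifications:
            fh.write(f"{c.node_ref}\t{c.assigned_label}\t{c.certainty:.6f}\t"
                     + "\t".join(f"{c.scores[l]:.6f}" for l in labels) + "\n")


def write_confusion_matrix(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(Path(path), sep="\t", index_label="auto\\manual")


def read_confusion_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    return df
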