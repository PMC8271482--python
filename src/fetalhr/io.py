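"""CSV readers/writers and pipeline configuration.

Recordings travel as plain CSV: a comment header carrying the sampling
metadata (``# fs=1000 adc_bits=14 full_scale_v=0.016``), a column-name
row, then one column per channel.  Reset logs are sidecar CSVs
(``channel,sample``) discovered next to the recording, and annotations are
``sample,source`` CSVs.  Non-1000 Hz recordings are resampled on load.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .maternal import QrsAnnotation
from .preprocess import FilterSpec, ResetEvent, UnipolarRecording

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "read_annotation",
    "write_annotation",
]

TARGET_FS = 1000.0


@dataclass
class PipelineConfig:
    """All tunable constants of the estimation pipeline.

    Defaults are the validated operating point: QRS band limits, the
    a-posteriori maternal selection constants (rate range [50, 180] bpm,
    nominal 85 bpm), the 5x-median artifact-cycle threshold, the rank of
    the maternal SVD template (``svd_rank``), the 10 s / 5 s block
    geometry, the fetal rate range [100, 180] bpm, and the 50 ms beat
    matching tolerance.
    """

    notch_freq: float = 50.0
    notch_bw: float = 1.0
    lp_cutoff: float = 75.0
    lp_order: int = 200
    hp_cutoff: float = 10.0
    hp_order: int = 6
    reset_window_ms: float = 50.0
    mqrs_band: tuple[float, float] = (6.3, 16.0)
    maternal_rate_range: tuple[float, float] = (50.0, 180.0)
    maternal_ref_bpm: float = 85.0
    artifact_multiplier: float = 5.0
    reject_artifact_cycles: bool = True
    svd_rank: int = 2
    fetal_rate_range: tuple[float, float] = (100.0, 180.0)
    segment_s: float = 10.0
    step_s: float = 5.0
    match_tolerance_ms: float = 50.0
    buffer_s: float = 60.0
    min_tail_s: float = 30.0
    seed: int = 0

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            notch_freq=self.notch_freq,
            notch_bw=self.notch_bw,
            lp_cutoff=self.lp_cutoff,
            lp_order=self.lp_order,
            hp_cutoff=self.hp_cutoff,
            hp_order=self.hp_order,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["mqrs_band"] = list(d["mqrs_band"])
        d["maternal_rate_range"] = list(d["maternal_rate_range"])
        d["fetal_rate_range"] = list(d["fetal_rate_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("mqrs_band", "maternal_rate_range", "fetal_rate_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @property
    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_recording(rec: UnipolarRecording, path: str | Path) -> None:
    path = Path(path)
    header = f"# fs={rec.fs:g} adc_bits={rec.adc_bits} full_scale_v={rec.full_scale_v:g}\n"
    cols = ",".join(f"ch{i + 1}" for i in range(rec.n_channels))
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(cols + "\n")
        np.savetxt(fh, rec.x.T, delimiter=",", fmt="%.17g")
    if rec.reset_events:
        sidecar = path.with_suffix(".resets.csv")
        with open(sidecar, "w") as fh:
            fh.write("channel,sample\n")
            for ev in rec.reset_events:
                fh.write(f"{ev.channel},{ev.sample}\n")


def _parse_header(line: str) -> dict[str, float]:
    meta: dict[str, float] = {}
    for token in line.lstrip("#").split():
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = float(v)
    return meta


def read_recording(path: str | Path, resample_to: float = TARGET_FS) -> UnipolarRecording:
    """Read a CSV recording (+ reset sidecar if present).

    Errors on a missing ``fs`` header or a channel count other than 4
    (the estimator is specific to the 4-electrode abdominal montage).
    Recordings at other rates are resampled to ``resample_to``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing '# fs=...' metadata header")
    meta = _parse_header(first)
    if "fs" not in meta:
        raise ValueError(f"{path}: header does not declare fs")
    df = pd.read_csv(path, skiprows=1, float_precision="round_trip")
    if df.shape[1] != 4:
        raise ValueError(
            f"{path}: expected 4 unipolar channels (abdominal montage), got {df.shape[1]}"
        )
    x = df.to_numpy(dtype=float).T
    fs = float(meta["fs"])
    events: list[ResetEvent] = []
    sidecar = path.with_suffix(".resets.csv")
    if sidecar.exists():
        rdf = pd.read_csv(sidecar)
        events = [
            ResetEvent(channel=int(r.channel), sample=int(r.sample))
            for r in rdf.itertuples()
        ]
    if fs != resample_to:
        from scipy.signal import resample_poly
        from fractions import Fraction

        frac = Fraction(int(round(resample_to)), int(round(fs)))
        log.info("resampling %s from %g Hz to %g Hz", path.name, fs, resample_to)
        x = resample_poly(x, frac.numerator, frac.denominator, axis=1)
        scale = resample_to / fs
        events = [ResetEvent(e.channel, int(round(e.sample * scale))) for e in events]
        fs = resample_to
    return UnipolarRecording(
        x=x,
        fs=fs,
        adc_bits=int(meta.get("adc_bits", 14)),
        reset_events=events,
        full_scale_v=float(meta.get("full_scale_v", 0.016)),
    )


def write_annotation(ann: QrsAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample,source\n")
        for s in ann.samples:
            fh.write(f"{s},{ann.source}\n")


def read_annotation(path: str | Path, fs: float = TARGET_FS) -> QrsAnnotation:
    df = pd.read_csv(path)
    source = str(df["source"].iloc[0]) if "source" in df and len(df) else "fetal"
    return QrsAnnotation(df["sample"].to_numpy(dtype=int), fs, source=source)
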