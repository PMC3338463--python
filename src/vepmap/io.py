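"""File formats.

* Electrode positions: ``.sfp`` whitespace files (label x y z, mm) and a TSV
  dialect; fiducial rows labeled ``nasion``/``lpa``/``rpa``.
* Continuous EEG: BrainVision triplet (``.vhdr``/``.vmrk``/``.eeg``, IEEE
  float32 multiplexed) and an HDF5 fallback carrying the same content.
* Evoked responses: HDF5.
* Head model: YAML block (``radius_mm``, ``ratios``,
  ``conductivities_S_per_m``, ``series_order``).
* Source models: TSV with a JSON sidecar for optimizer metadata.
* Volumes: NIfTI-1 via nibabel.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .dipole_fit import DipoleSource, SourceModel
from .fmri_stats import VolumeSeries
from .forward_model import ElectrodeMontage, HeadModel
from .vep_pipeline import EvokedResponse, RawRecording

__all__ = [
    "read_sfp", "write_sfp", "read_electrodes_tsv", "write_electrodes_tsv",
    "read_head_model_yaml", "write_head_model_yaml",
    "write_brainvision", "read_brainvision",
    "write_raw_h5", "read_raw_h5",
    "write_evoked_h5", "read_evoked_h5",
    "write_source_model", "read_source_model",
    "write_nifti", "read_nifti",
]

_FIDUCIALS = ("nasion", "lpa", "rpa")


# ---------------------------------------------------------------- electrodes


def write_sfp(path, montage: ElectrodeMontage) -> None:
    with open(path, "w") as fh:
        for name, pos in montage.fiducials.items():
            fh.write(f"{name} {pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f}\n")
        for lab, pos in zip(montage.labels, montage.positions):
            fh.write(f"{lab} {pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f}\n")


def read_sfp(path) -> ElectrodeMontage:
    labels, positions, fiducials = [], [], {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 4:
                raise ValueError(f"malformed electrode line: {line!r}")
            name, xyz = parts[0], [float(v) for v in parts[1:]]
            if name.lower() in _FIDUCIALS:
                fiducials[name.lower()] = np.array(xyz)
            else:
                labels.append(name)
                positions.append(xyz)
    return ElectrodeMontage(labels=labels, positions=np.array(positions),
                            fiducials=fiducials)


def write_electrodes_tsv(path, montage: ElectrodeMontage) -> None:
    with open(path, "w") as fh:
        fh.write("label\tx_mm\ty_mm\tz_mm\n")
        for name, pos in montage.fiducials.items():
            fh.write(f"{name}\t{pos[0]:.4f}\t{pos[1]:.4f}\t{pos[2]:.4f}\n")
        for lab, pos in zip(montage.labels, montage.positions):
            fh.write(f"{lab}\t{pos[0]:.4f}\t{pos[1]:.4f}\t{pos[2]:.4f}\n")


def read_electrodes_tsv(path) -> ElectrodeMontage:
    labels, positions, fiducials = [], [], {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("label"):
            raise ValueError("TSV electrode file must start with a header row")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                continue
            name, xyz = parts[0], [float(v) for v in parts[1:]]
            if name.lower() in _FIDUCIALS:
                fiducials[name.lower()] = np.array(xyz)
            else:
                labels.append(name)
                positions.append(xyz)
    return ElectrodeMontage(labels=labels, positions=np.array(positions),
                            fiducials=fiducials)


# ---------------------------------------------------------------- head model


def write_head_model_yaml(path, head: HeadModel) -> None:
    doc = {
        "head_model": {
            "radius_mm": head.outer_radius,
            "ratios": list(head.shell_ratios),
            "conductivities_S_per_m": list(head.conductivities),
            "series_order": head.series_order,
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_head_model_yaml(path) -> HeadModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    block = doc.get("head_model", doc)
    return HeadModel(
        outer_radius=float(block["radius_mm"]),
        shell_ratios=tuple(block["ratios"]),
        conductivities=tuple(block["conductivities_S_per_m"]),
        series_order=int(block.get("series_order", 100)),
    )


# ---------------------------------------------------------------- BrainVision


def write_brainvision(basename, raw: RawRecording) -> None:
    """Write a BrainVision triplet (float32 multiplexed binary)."""
    base = Path(basename)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch = raw.data.shape[0]
    with open(vhdr, "w") as fh:
        fh.write("Brain Vision Data Exchange Header File Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={eeg.name}\nMarkerFile={vmrk.name}\n")
        fh.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        fh.write(f"NumberOfChannels={n_ch}\n")
        fh.write(f"SamplingInterval={1e6 / raw.sfreq:.6f}\n\n")
        fh.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n")
        fh.write("[Channel Infos]\n")
        for i, lab in enumerate(raw.labels, 1):
            fh.write(f"Ch{i}={lab},,1,µV\n")
    with open(vmrk, "w") as fh:
        fh.write("Brain Vision Data Exchange Marker File, Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={eeg.name}\n\n[Marker Infos]\n")
        fh.write("Mk1=New Segment,,1,1,0\n")
        for i, (sample, cond) in enumerate(raw.events, 2):
            fh.write(f"Mk{i}=Stimulus,{cond},{sample + 1},1,0\n")
    raw.data.T.astype("<f4").tofile(eeg)


def read_brainvision(vhdr_path) -> RawRecording:
    """Minimal BrainVision reader (float32/int16, multiplexed)."""
    vhdr_path = Path(vhdr_path)
    sections: dict[str, dict] = {}
    chan_rows: list[str] = []
    current = None
    for line in vhdr_path.read_text(encoding="utf-8", errors="replace").splitlines():
        line = line.strip()
        if not line or line.startswith((";", "#")):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
            continue
        if "=" in line and current is not None:
            k, v = line.split("=", 1)
            sections[current][k.strip()] = v.strip()
            if current == "Channel Infos":
                chan_rows.append(v.strip())
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only multiplexed BrainVision data are supported")
    fmt = binary.get("BinaryFormat", "IEEE_FLOAT_32").upper()
    dtype = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}.get(fmt)
    if dtype is None:
        raise ValueError(f"unsupported BinaryFormat {fmt}")
    sfreq = 1e6 / float(common["SamplingInterval"])
    labels, scales = [], []
    for row in chan_rows:
        parts = row.split(",")
        labels.append(parts[0])
        scales.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
    data = np.fromfile(vhdr_path.parent / common["DataFile"], dtype=dtype)
    n_ch = len(labels)
    data = data.reshape(-1, n_ch).T.astype(float) * np.array(scales)[:, None]

    events = []
    mrk_file = common.get("MarkerFile")
    if mrk_file and (vhdr_path.parent / mrk_file).exists():
        for line in (vhdr_path.parent / mrk_file).read_text().splitlines():
            if not line.startswith("Mk") or "=" not in line:
                continue
            fields = line.split("=", 1)[1].split(",")
            if fields[0] != "Stimulus":
                continue
            events.append((int(fields[2]) - 1, fields[1]))
    return RawRecording(data=data, sfreq=sfreq, labels=labels, events=events)


# ---------------------------------------------------------------- HDF5 raw


def write_raw_h5(path, raw: RawRecording) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=raw.data, compression="gzip", shuffle=True)
        fh.attrs["sfreq"] = raw.sfreq
        fh.create_dataset(
            "labels", data=np.array(raw.labels, dtype=h5py.string_dtype())
        )
        if raw.events:
            fh.create_dataset("event_samples",
                              data=np.array([s for s, _ in raw.events], dtype=np.int64))
            fh.create_dataset(
                "event_conditions",
                data=np.array([c for _, c in raw.events], dtype=h5py.string_dtype()),
            )


def read_raw_h5(path) -> RawRecording:
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        sfreq = float(fh.attrs["sfreq"])
        labels = [s.decode() if isinstance(s, bytes) else s for s in fh["labels"][()]]
        events = []
        if "event_samples" in fh:
            conds = [
                s.decode() if isinstance(s, bytes) else s
                for s in fh["event_conditions"][()]
            ]
            events = list(zip((int(v) for v in fh["event_samples"][()]), conds))
    return RawRecording(data=data, sfreq=sfreq, labels=labels, events=events)


# ---------------------------------------------------------------- evoked


def write_evoked_h5(path, evoked: EvokedResponse) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=evoked.data)
        fh.attrs["sfreq"] = evoked.sfreq
        fh.attrs["t0_offset_ms"] = evoked.t0_offset_ms
        fh.attrs["condition"] = evoked.condition
        fh.attrs["n_trials_averaged"] = evoked.n_trials_averaged
        fh.create_dataset(
            "labels", data=np.array(evoked.labels, dtype=h5py.string_dtype())
        )
        fh.create_dataset(
            "provenance",
            data=np.array(evoked.provenance, dtype=h5py.string_dtype()),
        )


def read_evoked_h5(path) -> EvokedResponse:
    with h5py.File(path, "r") as fh:
        return EvokedResponse(
            data=fh["data"][()],
            sfreq=float(fh.attrs["sfreq"]),
            t0_offset_ms=float(fh.attrs["t0_offset_ms"]),
            labels=[
                s.decode() if isinstance(s, bytes) else s for s in fh["labels"][()]
            ],
            condition=str(fh.attrs["condition"]),
            n_trials_averaged=int(fh.attrs["n_trials_averaged"]),
            provenance=[
                s.decode() if isinstance(s, bytes) else s
                for s in fh["provenance"][()]
            ],
        )


# ---------------------------------------------------------------- source model


def write_source_model(path, model: SourceModel, json_sidecar: bool = True) -> None:
    """TSV: label, position, orientation, window and RV columns."""
    path = Path(path)
    win_info = {w[0]: (w[1], w[2]) for w in model.meta.get("windows", [])}
    rv_before = {r.get("window"): r.get("rv_before") for r in model.window_report}
    rv_after = {r.get("window"): r.get("rv_after", r.get("rv")) for r in model.window_report}
    with open(path, "w") as fh:
        fh.write(
            "label\tx\ty\tz\tox\toy\toz\twindow_start\twindow_end"
            "\trv_before\trv_after\tseed_roi\n"
        )
        for d in model.dipoles:
            w = win_info.get(d.label, (np.nan, np.nan))
            rb = rv_before.get(d.label)
            ra = rv_after.get(d.label)
            fh.write(
                f"{d.label}\t{d.position[0]:.3f}\t{d.position[1]:.3f}"
                f"\t{d.position[2]:.3f}\t{d.orientation[0]:.6f}"
                f"\t{d.orientation[1]:.6f}\t{d.orientation[2]:.6f}"
                f"\t{w[0]:g}\t{w[1]:g}"
                f"\t{'' if rb is None else format(rb, '.4f')}"
                f"\t{'' if ra is None else format(ra, '.4f')}"
                f"\t{d.seed_roi or ''}\n"
            )
    if json_sidecar:
        meta = dict(model.meta)
        meta["total_rv"] = model.total_rv
        meta["total_window_ms"] = list(model.total_window_ms)
        meta["window_report"] = [
            {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
             for k, v in r.items()}
            for r in model.window_report
        ]
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def read_source_model(path) -> SourceModel:
    import pandas as pd

    tab = pd.read_csv(path, sep="\t")
    dipoles = [
        DipoleSource(
            position=np.array([r.x, r.y, r.z]),
            orientation=np.array([r.ox, r.oy, r.oz]),
            label=str(r.label),
            seed_roi=None if pd.isna(r.seed_roi) else str(r.seed_roi),
        )
        for r in tab.itertuples()
    ]
    meta = {}
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SourceModel(
        dipoles=dipoles,
        waveforms=None,
        times_ms=None,
        total_rv=float(meta.get("total_rv", np.nan)),
        meta=meta,
    )


# ---------------------------------------------------------------- volumes


def write_nifti(path, series: VolumeSeries) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header.set_zooms(tuple(np.abs(np.diag(series.affine))[:3]) + (series.tr,))
    nib.save(img, str(path))


def read_nifti(path, tr: float | None = None, n_discarded_initial: int = 4) -> VolumeSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    zooms = img.header.get_zooms()
    tr = tr if tr is not None else (float(zooms[3]) if len(zooms) > 3 else 2.0)
    return VolumeSeries(
        data=data,
        tr=tr,
        affine=np.asarray(img.affine),
        voxel_size_mm=float(zooms[0]),
        n_discarded_initial=n_discarded_initial,
    )
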