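"""Standard-format output: NIfTI images, k-space containers, YAML
configs, provenance JSON, waveform TSV."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .imperfections import EddyTerm, ImperfectionModel, ResonantTerm
from .signal import KSpaceData
from .waveforms import ProtocolSpec

__all__ = [
    "save_complex_nifti",
    "load_complex_nifti",
    "save_kspace",
    "load_kspace",
    "write_provenance",
    "protocol_from_dict",
    "model_from_dict",
    "load_config",
]


def save_complex_nifti(image: np.ndarray, path, fov_mm: float, parts: str = "magphase") -> list[Path]:
    """Write a complex image as NIfTI pairs (readout = first image axis).

    ``parts`` is ``magphase`` or ``realimag``; returns the written paths.
    """
    path = Path(path)
    N = image.shape[-1]
    vox = fov_mm / N
    affine = np.diag([vox, vox, 1.0, 1.0])
    arr = np.asarray(image).T  # internal [y, x] -> file [x(read), y(phase)]
    if parts == "magphase":
        pieces = {"mag": np.abs(arr), "phase": np.angle(arr)}
    elif parts == "realimag":
        pieces = {"real": arr.real, "imag": arr.imag}
    else:
        raise ValueError("parts must be 'magphase' or 'realimag'")
    written = []
    for suffix, data in pieces.items():
        p = path.with_name(f"{path.stem}_{suffix}.nii.gz")
        nib.save(nib.Nifti1Image(np.ascontiguousarray(data, dtype=np.float64), affine), p)
        written.append(p)
    return written


def load_complex_nifti(stem) -> np.ndarray:
    stem = Path(stem)
    mag = nib.load(stem.with_name(f"{stem.stem}_mag.nii.gz")).get_fdata()
    phase = nib.load(stem.with_name(f"{stem.stem}_phase.nii.gz")).get_fdata()
    return (mag * np.exp(1j * phase)).T


def save_kspace(data: KSpaceData, path) -> Path:
    """Named-array container (.npz) plus a JSON sidecar of provenance."""
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(
        path,
        samples=data.samples,
        kx_nominal=data.kx_nominal,
        kx_actual=data.kx_actual,
        ky_index=data.ky_index,
        t_us=data.t_us,
        line_parity=data.line_parity,
        acs_mask=np.array([]) if data.acs_mask is None else data.acs_mask,
    )
    sidecar = {
        "train_polarity": data.train_polarity,
        "matrix_size": data.matrix_size,
        "fov_mm": data.fov_mm,
        "grappa_factor": data.grappa_factor,
        "is_reference": data.is_reference,
        "provenance": data.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def load_kspace(path) -> KSpaceData:
    path = Path(path).with_suffix(".npz")
    z = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    acs = z["acs_mask"]
    return KSpaceData(
        samples=z["samples"],
        kx_nominal=z["kx_nominal"],
        kx_actual=z["kx_actual"],
        ky_index=z["ky_index"],
        t_us=z["t_us"],
        line_parity=z["line_parity"],
        train_polarity=int(meta["train_polarity"]),
        matrix_size=int(meta["matrix_size"]),
        fov_mm=float(meta["fov_mm"]),
        grappa_factor=int(meta["grappa_factor"]),
        acs_mask=None if acs.size == 0 else acs.astype(bool),
        is_reference=bool(meta["is_reference"]),
        provenance=meta.get("provenance", {}),
    )


def write_provenance(path, **entries) -> Path:
    path = Path(path)
    path.write_text(json.dumps(entries, indent=2, sort_keys=True, default=str))
    return path


_PROTOCOL_KEYS = {
    "matrix_size", "fov_mm", "echo_spacing_ms", "dwell_us", "gmax_mT_per_m",
    "smax_T_per_m_per_s", "ramp_sampling", "grappa_factor", "acs_lines",
    "train_polarity", "te_ms",
}


def protocol_from_dict(d: dict) -> ProtocolSpec:
    unknown = set(d) - _PROTOCOL_KEYS
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    missing = {"matrix_size", "fov_mm", "echo_spacing_ms"} - set(d)
    if missing:
        raise ValueError(f"protocol requires keys: {sorted(missing)}")
    return ProtocolSpec(**d)


def model_from_dict(d: dict) -> ImperfectionModel:
    """Imperfection model from the YAML schema:

    .. code-block:: yaml

        eddy: [{a: 0.003, tau_us: 70.0}, ...]
        resonance: {f0_hz: 1100.0, width_hz: 150.0, coupling: 0.02, enabled: true}
        delay_us: 0.0
    """
    unknown = set(d) - {"eddy", "resonance", "delay_us"}
    if unknown:
        raise ValueError(f"unknown imperfection keys: {sorted(unknown)}")
    terms = tuple(
        EddyTerm(float(t["a"]), float(t["tau_us"])) for t in d.get("eddy", [])
    )
    res = None
    if "resonance" in d:
        r = d["resonance"]
        res = ResonantTerm(
            f0_Hz=float(r.get("f0_hz", 1100.0)),
            q_width_Hz=float(r.get("width_hz", 150.0)),
            coupling=float(r.get("coupling", 0.0)),
            enabled=bool(r.get("enabled", True)),
        )
    return ImperfectionModel(
        eddy_terms=terms, resonant=res, delay_us=float(d.get("delay_us", 0.0))
    )


def load_config(path) -> dict:
    """Load and structurally validate an experiment YAML config.

    Recognized top-level sections: ``protocol``, ``imperfections``,
    ``phantom``, ``seed``, ``out_dir``. Returns a dict with parsed
    ``protocol`` / ``model`` objects alongside the raw values.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"protocol", "imperfections", "phantom", "seed", "out_dir"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = dict(raw)
    if "protocol" in raw:
        out["protocol"] = protocol_from_dict(raw["protocol"])
    if "imperfections" in raw:
        out["model"] = model_from_dict(raw["imperfections"])
    return out
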