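"""File formats: protocol JSON, timing summary tables, dataset archives,
fit CSVs and optional NIfTI export."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .inference import FitResults
from .protocols import ProtocolSpec, duration_str, scan_accounting
from .simulator import NoiseModel, SimulatedDataset

__all__ = [
    "save_protocol",
    "load_protocol",
    "protocol_summary",
    "save_dataset",
    "load_dataset",
    "fits_to_frame",
    "write_csv",
    "config_hash",
    "dataset_to_nifti",
]


def save_protocol(spec: ProtocolSpec, path) -> None:
    payload = {
        "family": spec.family,
        "lds": spec.lds if isinstance(spec.lds, list) else list(spec.lds),
        "plds": list(spec.plds),
        "encoding_rows": spec.encoding_rows,
        "n_ave": spec.n_ave,
        "overhead": spec.overhead,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_protocol(path) -> ProtocolSpec:
    payload = json.loads(Path(path).read_text())
    return ProtocolSpec(**payload)  # dataclass validation enforces invariants


def _fmt_ms(values) -> str:
    if values and isinstance(values[0], (list, tuple)):
        return "; ".join(_fmt_ms(list(v)) for v in values)
    return ", ".join(str(int(round(v * 1000))) for v in values)


def protocol_summary(specs: Dict[str, ProtocolSpec]) -> pd.DataFrame:
    """Timing summary: LDs/PLDs in ms, N_T, N_Ave, N_Acq and duration."""
    rows = []
    for name, p in specs.items():
        acc = scan_accounting(p)
        rows.append({
            "protocol": name,
            "label_durations_ms": _fmt_ms(list(p.lds)),
            "plds_ms": _fmt_ms(list(p.plds)),
            "n_t": p.n_timepoints(),
            "n_ave": p.n_ave,
            "n_acq": acc.n_acq,
            "duration": duration_str(acc.total_duration),
        })
    return pd.DataFrame(rows).set_index("protocol")


def save_dataset(ds: SimulatedDataset, path) -> None:
    """Columnar archive: volumes + ATT grid + JSON metadata sidecar string."""
    meta = {
        "protocol": {
            "family": ds.protocol.family,
            "lds": ds.protocol.lds if isinstance(ds.protocol.lds, list)
            else list(ds.protocol.lds),
            "plds": list(ds.protocol.plds),
            "encoding_rows": ds.protocol.encoding_rows,
            "n_ave": ds.protocol.n_ave,
            "overhead": ds.protocol.overhead,
        },
        "cbf_true": ds.cbf_true,
        "noise": asdict(ds.noise),
        "seed": None if ds.seed is None else int(ds.seed),
    }
    np.savez_compressed(
        path, volumes=ds.volumes, att=ds.att, meta=json.dumps(meta)
    )


def load_dataset(path) -> SimulatedDataset:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return SimulatedDataset(
            protocol=ProtocolSpec(**meta["protocol"]),
            att=z["att"],
            cbf_true=meta["cbf_true"],
            volumes=z["volumes"],
            noise=NoiseModel(**meta["noise"]),
            seed=meta["seed"],
        )


def fits_to_frame(fits: FitResults, att: np.ndarray,
                  protocol: Optional[str] = None) -> pd.DataFrame:
    """Flatten batched (n_att, replicas) fit results to a tidy table."""
    n_att, reps = fits.cbf_mean.shape
    df = pd.DataFrame({
        "att_true": np.repeat(np.asarray(att), reps),
        "replica": np.tile(np.arange(reps), n_att),
        "cbf_mean": fits.cbf_mean.ravel(),
        "cbf_sd": fits.cbf_sd.ravel(),
        "att_mean": fits.att_mean.ravel(),
        "att_sd": fits.att_sd.ravel(),
        "converged": fits.converged.ravel(),
    })
    if protocol is not None:
        df.insert(0, "protocol", protocol)
    return df


def config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path, cfg_hash: Optional[str] = None,
              index: bool = True) -> None:
    """CSV with the run's config hash embedded as a comment header line."""
    with open(path, "w") as fh:
        if cfg_hash is not None:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def dataset_to_nifti(ds: SimulatedDataset, path) -> None:
    """Export as a 4D NIfTI volume: a synthetic voxel grid with one row of
    voxels per ATT sample (x = ATT sample, y = replica, z = 1, t = volume)."""
    import nibabel as nib

    data = ds.volumes[:, :, None, :].astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    nib.save(img, str(path))
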