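"""HDF5 trace container and CSV report I/O.

Layout: /recordings/<id>/response (and optional /stimulus, /spike_times)
with per-recording attributes (sampling_rate_hz, modality, background_rstar,
cone_type, retina_id, cell_id, units) and a /provenance group holding the
configuration snapshot, master seed and package version.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .recording import Recording

__all__ = ["write_container", "read_container", "export_csv", "SchemaError"]

REQUIRED_ATTRS = (
    "sampling_rate_hz",
    "modality",
    "background_rstar",
    "cone_type",
    "retina_id",
    "cell_id",
    "units",
)


class SchemaError(ValueError):
    """Raised when a container violates the trace schema."""


def write_container(
    recordings: dict | list,
    path,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write recordings to an HDF5 container with provenance.

    ``recordings`` is a mapping id -> Recording (a list gets enumerated ids).
    """
    from . import __version__

    if isinstance(recordings, list):
        recordings = {f"rec{i:05d}": r for i, r in enumerate(recordings)}
    path = Path(path)
    with h5py.File(path, "w") as h5:
        grp = h5.create_group("recordings")
        for rec_id, rec in recordings.items():
            g = grp.create_group(str(rec_id))
            g.create_dataset("response", data=rec.samples)
            if rec.stimulus is not None and isinstance(rec.stimulus, np.ndarray):
                g.create_dataset("stimulus", data=rec.stimulus)
            spike_times = rec.meta.get("spike_times")
            if spike_times is not None:
                g.create_dataset("spike_times", data=np.asarray(spike_times))
            g.attrs["sampling_rate_hz"] = rec.sampling_rate
            g.attrs["modality"] = rec.modality
            g.attrs["background_rstar"] = rec.background
            g.attrs["cone_type"] = rec.cone_type
            g.attrs["retina_id"] = rec.retina_id
            g.attrs["cell_id"] = rec.cell_id
            g.attrs["units"] = rec.units
        prov = h5.create_group("provenance")
        prov.attrs["package_version"] = __version__
        prov.attrs["schema_version"] = 1
        if seed is not None:
            prov.attrs["seed"] = int(seed)
        if config is not None:
            prov.attrs["config"] = json.dumps(config, default=str)


def read_container(path) -> dict:
    """Read all recordings; raises SchemaError naming any offending path."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = {}
    with h5py.File(path, "r") as h5:
        if "recordings" not in h5:
            raise SchemaError(f"{path}: missing /recordings group")
        schema = h5.get("provenance", {})
        version = dict(getattr(schema, "attrs", {})).get("schema_version", 1)
        if version != 1:
            raise SchemaError(f"{path}: unsupported schema version {version}")
        for rec_id, g in h5["recordings"].items():
            for attr in REQUIRED_ATTRS:
                if attr not in g.attrs:
                    raise SchemaError(
                        f"{path}:/recordings/{rec_id} missing attribute {attr!r}"
                    )
            if "response" not in g:
                raise SchemaError(f"{path}:/recordings/{rec_id} missing response dataset")
            samples = g["response"][()]
            if not np.all(np.isfinite(samples)):
                raise SchemaError(f"{path}:/recordings/{rec_id} has non-finite samples")
            rec = Recording(
                samples=samples,
                sampling_rate=float(g.attrs["sampling_rate_hz"]),
                modality=str(g.attrs["modality"]),
                background=float(g.attrs["background_rstar"]),
                cone_type=str(g.attrs["cone_type"]),
                retina_id=str(g.attrs["retina_id"]),
                cell_id=str(g.attrs["cell_id"]),
                units=str(g.attrs["units"]),
                stimulus=g["stimulus"][()] if "stimulus" in g else None,
            )
            if "spike_times" in g:
                rec.meta["spike_times"] = g["spike_times"][()]
            out[rec_id] = rec
    return out


def read_provenance(path) -> dict:
    with h5py.File(path, "r") as h5:
        if "provenance" not in h5:
            return {}
        attrs = dict(h5["provenance"].attrs)
    if "config" in attrs:
        attrs["config"] = json.loads(attrs["config"])
    return attrs


def export_csv(report: pd.DataFrame, path) -> None:
    """Write a tabular report with full float precision (lossless re-parse)."""
    pd.DataFrame(report).to_csv(path, index=False, float_format="%.17g")
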