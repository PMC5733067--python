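"""File-format front ends: raw readers, stat-table writers.

EDF is read through MNE's native reader (read-only interoperability); the
package's own format is the HDF5 array container with a JSON sidecar (see
:mod:`sourcetf.containers`).  Statistics are exported as plain TSV tables —
one row per voxel with grid-frame mm coordinates — plus a companion summary
listing the significant voxels ordered by |t|.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecord
from .forward import SourceSpace
from .stats import StatMap

__all__ = ["read_raw", "write_stat_table"]


def _read_edf(path: Path, sidecar: dict | None) -> ContinuousRecord:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    srate = float(raw.info["sfreq"])
    names = list(raw.ch_names)
    events = np.empty(0, dtype=int)
    if sidecar is not None:
        if "srate" in sidecar and abs(sidecar["srate"] - srate) > 1e-6:
            raise ValueError(
                f"sidecar srate {sidecar['srate']} does not match EDF header {srate}"
            )
        if "channel_names" in sidecar:
            declared = list(sidecar["channel_names"])
            if declared != names:
                if sorted(declared) != sorted(names):
                    raise ValueError("sidecar channel names do not match the EDF")
                order = [names.index(c) for c in declared]
                data = data[order]
                names = declared
        events = np.asarray(sidecar.get("events", []), dtype=int)
    return ContinuousRecord(data=data, srate=srate, channel_names=names, events=events)


def read_raw(path: str | Path, sidecar: str | Path | dict | None = None) -> ContinuousRecord:
    """Read a continuous record from EDF or the native array container.

    ``sidecar`` may be a dict or a path to a JSON file declaring ``srate``,
    ``channel_names`` and ``events``; for EDF it supplies event latencies
    and is cross-checked against the header, for the native container it is
    located automatically next to the array file.
    """
    path = Path(path)
    if isinstance(sidecar, (str, Path)):
        sidecar = json.loads(Path(sidecar).read_text())
    if path.suffix.lower() == ".edf":
        return _read_edf(path, sidecar)
    return ContinuousRecord.load(path)


def write_stat_table(
    stat_map: StatMap, source_space: SourceSpace, path: str | Path
) -> None:
    """Write per-voxel stats as TSV plus a ``*_summary.tsv`` of maxima.

    The main table has one row per voxel (x, y, z in grid-frame mm, t value,
    significance flag); the summary holds only the significant voxels,
    sorted by decreasing |t| so the maxima come first.
    """
    if len(stat_map.t) != source_space.n_voxels:
        raise ValueError(
            f"stat map has {len(stat_map.t)} voxels, source space "
            f"{source_space.n_voxels}"
        )
    path = Path(path)
    df = pd.DataFrame(
        {
            "x_mm": source_space.positions[:, 0],
            "y_mm": source_space.positions[:, 1],
            "z_mm": source_space.positions[:, 2],
            "t": stat_map.t,
            "significant": stat_map.mask.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    summary = df[df["significant"] == 1].copy()
    summary["abs_t"] = summary["t"].abs()
    summary = summary.sort_values("abs_t", ascending=False, kind="mergesort")
    summary = summary.drop(columns=["abs_t", "significant"])
    summary_path = path.with_name(path.stem + "_summary.tsv")
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.6g")
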