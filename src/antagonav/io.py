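"""Field / cohort / trace persistence.

Concentration slices go to NPZ with a JSON metadata sidecar; cohorts go to
HDF5 (one group per channel, vectorised layout); synthetic traces go to tidy
CSV so the analysis stages can round-trip them.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .navigator import CohortResult, ModelParams
from .plume_field import FieldSlice2D

__all__ = [
    "save_slice",
    "load_slice",
    "save_cohort",
    "load_cohort",
    "speed_series_to_csv",
    "calcium_traces_to_csv",
]


def save_slice(slc: FieldSlice2D, path) -> None:
    path = Path(path)
    np.savez_compressed(
        path, times=slc.times, x=slc.x, y=slc.y, values=slc.values,
        mask=slc.mask,
    )
    meta = {
        "plane_z": slc.plane_z,
        "radius": slc.radius,
        "source_xy": list(slc.source_xy),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_slice(path) -> FieldSlice2D:
    path = Path(path)
    data = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return FieldSlice2D(
        plane_z=meta["plane_z"],
        times=data["times"],
        x=data["x"],
        y=data["y"],
        values=data["values"],
        mask=data["mask"],
        radius=meta["radius"],
        source_xy=tuple(meta["source_xy"]),
    )


def save_cohort(result: CohortResult, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["condition"] = result.condition
        f.attrs["seed"] = result.seed
        f.attrs["source_xy"] = result.source_xy
        f.attrs["capture_radius"] = result.capture_radius
        f.attrs["plate_radius"] = result.plate_radius
        f.attrs["params"] = json.dumps(
            {k: v for k, v in result.params.__dict__.items()
             if isinstance(v, (int, float, str))}
        )
        for name in ("times", "positions", "headings", "speeds", "Q_H", "Q_T",
                     "capture_times", "taxis_counts"):
            f.create_dataset(name, data=getattr(result, name))


def load_cohort(path) -> CohortResult:
    with h5py.File(path, "r") as f:
        params_dict = json.loads(f.attrs["params"])
        params_dict.pop("taxis_threshold", None)
        return CohortResult(
            condition=str(f.attrs["condition"]),
            seed=int(f.attrs["seed"]),
            times=f["times"][:],
            positions=f["positions"][:],
            headings=f["headings"][:],
            speeds=f["speeds"][:],
            Q_H=f["Q_H"][:],
            Q_T=f["Q_T"][:],
            capture_times=f["capture_times"][:],
            taxis_counts=f["taxis_counts"][:],
            source_xy=tuple(f.attrs["source_xy"]),
            capture_radius=float(f.attrs["capture_radius"]),
            plate_radius=float(f.attrs["plate_radius"]),
            params=ModelParams(**{k: v for k, v in params_dict.items()
                                  if k in ModelParams.__dataclass_fields__}),
        )


def speed_series_to_csv(series, path) -> None:
    pd.DataFrame({"time_s": series.times, "speed_mm_s": series.values}).to_csv(
        path, index=False
    )


def calcium_traces_to_csv(traces, path) -> None:
    frames = []
    for i, tr in enumerate(traces):
        frames.append(pd.DataFrame({
            "worm": i,
            "time_s": tr.times,
            "gcamp": tr.gcamp,
            "reference": tr.reference,
            "label": tr.meta.get("label", ""),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
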