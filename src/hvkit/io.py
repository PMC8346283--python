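"""Reading and writing recordings and fit results.

A recording is stored as a wide tab-separated table (first column
``time_ms``, one column per test potential labeled by its value in mV)
plus a JSON metadata sidecar carrying the pH on each side, temperature,
protocol and provenance.  P/4 subsweeps, when present, go in a companion
``*_p4.tsv`` with columns ``<V>:<k>``.  The table round trip is
bit-stable: values are written with ``repr``-exact precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ephys import CurrentFamily, VoltageProtocol

__all__ = ["write_family", "read_family", "write_records", "read_records"]

_FLOAT_FMT = "%.17g"


def _family_frame(family: CurrentFamily) -> pd.DataFrame:
    data = {"time_ms": family.time_ms}
    for v in family.voltages:
        data[f"{v:g}"] = family.traces[float(v)]
    return pd.DataFrame(data)


def write_family(family: CurrentFamily, table_path, meta_path=None) -> None:
    """Write a current family as TSV + JSON sidecar (and ``*_p4.tsv``
    when subsweeps are present)."""
    table_path = Path(table_path)
    meta_path = Path(meta_path) if meta_path else table_path.with_suffix(".meta.json")
    _family_frame(family).to_csv(table_path, sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
    meta = {
        "metadata": family.metadata,
        "protocol": asdict(family.protocol),
    }
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    if family.subsweeps is not None:
        sub_data = {"time_ms": family.time_ms}
        for v, subs in family.subsweeps.items():
            for k, sub in enumerate(subs):
                sub_data[f"{v:g}:{k}"] = sub
        pd.DataFrame(sub_data).to_csv(
            _p4_path(table_path), sep="\t", index=False, float_format=_FLOAT_FMT
        )


def _p4_path(table_path: Path) -> Path:
    return table_path.with_name(table_path.stem + "_p4.tsv")


def read_family(table_path, meta_path=None) -> CurrentFamily:
    """Read a current family written by :func:`write_family`."""
    table_path = Path(table_path)
    meta_path = Path(meta_path) if meta_path else table_path.with_suffix(".meta.json")
    frame = pd.read_csv(table_path, sep="\t", float_precision="round_trip")
    meta = json.loads(meta_path.read_text())
    proto_dict = meta["protocol"]
    proto_dict["test_mV"] = tuple(proto_dict["test_mV"])
    protocol = VoltageProtocol(**proto_dict)
    time_ms = frame["time_ms"].to_numpy()
    traces = {
        float(col): frame[col].to_numpy()
        for col in frame.columns
        if col != "time_ms"
    }
    subsweeps = None
    p4 = _p4_path(table_path)
    if p4.exists():
        sub_frame = pd.read_csv(p4, sep="\t", float_precision="round_trip")
        subsweeps = {}
        for col in sub_frame.columns:
            if col == "time_ms":
                continue
            v_label, _ = col.rsplit(":", 1)
            subsweeps.setdefault(float(v_label), []).append(sub_frame[col].to_numpy())
    return CurrentFamily(
        protocol=protocol,
        time_ms=time_ms,
        traces=traces,
        metadata=meta["metadata"],
        subsweeps=subsweeps,
    )


def write_records(records: list[dict], path) -> None:
    """Write flat fit records (parameter, estimate, stderr, ...) as JSON."""
    Path(path).write_text(json.dumps(records, indent=2, default=_jsonable))


def read_records(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
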