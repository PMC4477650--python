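"""Readers and writers for the pipeline's tabular formats.

Traces travel as long-format CSV (trace_id, frame_index, donor, acceptor,
optional truth_state; frame time recorded in a ``# frame_s:`` header
comment) or as an equivalent HDF5 container (one group per trace, frame_s
as an attribute).  FRET, idealized-path and dwell tables are plain CSV;
gel lanes are band tables with per-row lane metadata columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

from .duplex import PrimerSpec
from .dwell import DwellSet
from .fret import FretTrace
from .hmm import IdealizedTrace
from .simulate import GelLane, Trace, TraceTruth

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_traces_hdf5",
    "read_traces_hdf5",
    "write_fret_csv",
    "read_fret_csv",
    "write_ideal_csv",
    "write_dwells_csv",
    "write_lanes_csv",
    "read_lanes_csv",
    "read_primers",
]


def _traces_frame(traces: Iterable[Trace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        df = pd.DataFrame(
            {
                "trace_id": tr.trace_id,
                "frame_index": np.arange(len(tr)),
                "donor": tr.donor,
                "acceptor": tr.acceptor,
            }
        )
        if tr.truth is not None:
            df["truth_state"] = tr.truth.state_path
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def write_traces_csv(traces: Iterable[Trace], path) -> None:
    traces = list(traces)
    frame_s = traces[0].frame_s
    with open(path, "w") as fh:
        fh.write(f"# frame_s: {frame_s}\n")
        _traces_frame(traces).to_csv(fh, index=False)


def read_traces_csv(path) -> list[Trace]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# frame_s:"):
            raise ValueError(f"{path}: missing '# frame_s:' header")
        frame_s = float(first.split(":", 1)[1])
        df = pd.read_csv(fh)
    traces = []
    for trace_id, group in df.groupby("trace_id", sort=False):
        truth = None
        if "truth_state" in group:
            truth = TraceTruth(
                state_path=group["truth_state"].to_numpy(dtype=np.int8),
                event=None,
                dwells=(),
                gamma_true=float("nan"),
            )
        traces.append(
            Trace(
                trace_id=str(trace_id),
                donor=group["donor"].to_numpy(float),
                acceptor=group["acceptor"].to_numpy(float),
                frame_s=frame_s,
                truth=truth,
            )
        )
    return traces


def write_traces_hdf5(traces: Iterable[Trace], path) -> None:
    with h5py.File(path, "w") as fh:
        for tr in traces:
            grp = fh.create_group(tr.trace_id)
            grp.attrs["frame_s"] = tr.frame_s
            grp.create_dataset("donor", data=tr.donor)
            grp.create_dataset("acceptor", data=tr.acceptor)
            if tr.truth is not None:
                grp.create_dataset("truth_state", data=tr.truth.state_path)


def read_traces_hdf5(path) -> list[Trace]:
    traces = []
    with h5py.File(path, "r") as fh:
        for trace_id in fh:
            grp = fh[trace_id]
            truth = None
            if "truth_state" in grp:
                truth = TraceTruth(
                    state_path=grp["truth_state"][...].astype(np.int8),
                    event=None,
                    dwells=(),
                    gamma_true=float("nan"),
                )
            traces.append(
                Trace(
                    trace_id=trace_id,
                    donor=grp["donor"][...],
                    acceptor=grp["acceptor"][...],
                    frame_s=float(grp.attrs["frame_s"]),
                    truth=truth,
                )
            )
    return traces


def write_fret_csv(frets: Iterable[FretTrace], path) -> None:
    frets = list(frets)
    frame_s = frets[0].frame_s
    rows = []
    for ft in frets:
        in_event = np.zeros(len(ft), dtype=bool)
        for s, e in ft.events:
            in_event[s:e] = True
        rows.append(
            pd.DataFrame(
                {
                    "trace_id": ft.trace_id,
                    "frame_index": np.arange(len(ft)),
                    "efficiency": ft.efficiencies,
                    "in_event": in_event,
                    "gamma_hat": ft.gamma_hat,
                }
            )
        )
    with open(path, "w") as fh:
        fh.write(f"# frame_s: {frame_s}\n")
        pd.concat(rows, ignore_index=True).to_csv(fh, index=False)


def read_fret_csv(path) -> list[FretTrace]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# frame_s:"):
            raise ValueError(f"{path}: missing '# frame_s:' header")
        frame_s = float(first.split(":", 1)[1])
        df = pd.read_csv(fh)
    frets = []
    for trace_id, group in df.groupby("trace_id", sort=False):
        in_event = group["in_event"].to_numpy(bool)
        padded = np.concatenate(([False], in_event, [False])).astype(int)
        diff = np.diff(padded)
        events = tuple(
            (int(s), int(e))
            for s, e in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1))
        )
        frets.append(
            FretTrace(
                trace_id=str(trace_id),
                efficiencies=group["efficiency"].to_numpy(float),
                frame_s=frame_s,
                gamma_hat=float(group["gamma_hat"].iloc[0]),
                events=events,
            )
        )
    return frets


def write_ideal_csv(ideals: Iterable[IdealizedTrace], frets: Iterable[FretTrace], path) -> None:
    ideals, frets = list(ideals), list(frets)
    rows = []
    for ideal, ft in zip(ideals, frets):
        in_event = np.zeros(len(ideal.state_path), dtype=bool)
        for s, e in ft.events:
            in_event[s:e] = True
        mapping = ideal.mapping or {}
        rows.append(
            pd.DataFrame(
                {
                    "trace_id": ideal.trace_id,
                    "frame_index": np.arange(len(ideal.state_path)),
                    "state": ideal.state_path,
                    "semantic_label": [mapping.get(int(s), str(s)) for s in ideal.state_path],
                    "in_event": in_event,
                }
            )
        )
    with open(path, "w") as fh:
        fh.write(f"# frame_s: {ideals[0].frame_s}\n")
        pd.concat(rows, ignore_index=True).to_csv(fh, index=False)


def write_dwells_csv(dwells: DwellSet, path) -> None:
    pd.DataFrame(
        {
            "trace_id": [d.trace_id for d in dwells.dwells],
            "event_index": [d.event_index for d in dwells.dwells],
            "state": [d.state for d in dwells.dwells],
            "duration_s": [d.duration_s for d in dwells.dwells],
            "censored": [d.censored for d in dwells.dwells],
        }
    ).to_csv(path, index=False)


def write_lanes_csv(lanes: Iterable[GelLane], path) -> None:
    rows = []
    for lane in lanes:
        for length, intensity in lane.bands:
            rows.append(
                {
                    "primer": lane.primer_name,
                    "product_length": length,
                    "intensity": intensity,
                    "recovery_control": lane.recovery_control_intensity,
                    "first_repeat_length": lane.first_repeat_length,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lanes_csv(path) -> list[GelLane]:
    df = pd.read_csv(path)
    lanes = []
    for primer, group in df.groupby("primer", sort=False):
        group = group.sort_values("product_length")
        lanes.append(
            GelLane(
                primer_name=str(primer),
                bands=tuple(
                    (int(l), float(i))
                    for l, i in zip(group["product_length"], group["intensity"])
                ),
                recovery_control_intensity=float(group["recovery_control"].iloc[0]),
                first_repeat_length=int(group["first_repeat_length"].iloc[0]),
            )
        )
    return lanes


def read_primers(path) -> list[PrimerSpec]:
    """Primers from FASTA (by extension .fa/.fasta) or two-column CSV
    (name, sequence)."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        return [
            PrimerSpec(name=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    df = pd.read_csv(path)
    name_col, seq_col = df.columns[:2]
    return [
        PrimerSpec(name=str(n), sequence=str(s).upper())
        for n, s in zip(df[name_col], df[seq_col])
    ]
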