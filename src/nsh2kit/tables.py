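"""Plain-text tables for work sets, umbrella windows, and pull traces.

All files are whitespace-separated columns with ``#``-prefixed header lines;
the work-table header states the sign convention explicitly to prevent
silent sign errors when sets are exchanged between tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model_systems import WorkSet
from .wham import UmbrellaWindow, UmbrellaWindowSet

__all__ = [
    "write_work_table",
    "read_work_table",
    "write_window_set",
    "read_window_set",
    "write_pull_trace",
    "read_pull_trace",
]


def write_work_table(work: WorkSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# nsh2kit work table; columns: direction(F|R) work_kJmol\n")
        fh.write("# sign convention: forward work = work done on the system "
                 "for the 0->1 switch; reverse for 1->0\n")
        fh.write(f"# temperature_K = {work.temperature}\n")
        if work.true_dg is not None:
            fh.write(f"# true_dg_kJmol = {work.true_dg}\n")
        for w in work.forward_work:
            fh.write(f"F {w:.8f}\n")
        for w in work.reverse_work:
            fh.write(f"R {w:.8f}\n")


def read_work_table(path) -> WorkSet:
    temperature, true_dg = 300.0, None
    forward, reverse = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "temperature_K" in line:
                    temperature = float(line.split("=")[1])
                elif "true_dg_kJmol" in line:
                    true_dg = float(line.split("=")[1])
                continue
            direction, value = line.split()
            if direction == "F":
                forward.append(float(value))
            elif direction == "R":
                reverse.append(float(value))
            else:
                raise ValueError(f"unknown work direction {direction!r}")
    return WorkSet(np.array(forward), np.array(reverse),
                   temperature=temperature, true_dg=true_dg)


def write_window_set(windows: UmbrellaWindowSet, directory) -> None:
    """Per-window two-column time/value sample tables plus JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"temperature_K": windows.temperature, "windows": []}
    for i, w in enumerate(windows.windows):
        fname = f"window_{i:03d}.dat"
        with open(directory / fname, "w") as fh:
            fh.write("# umbrella window samples; columns: time_ps xi_nm\n")
            fh.write(f"# ref_nm = {w.ref}; k_kJmol_nm2 = {w.k}\n")
            for t, x in enumerate(w.samples):
                fh.write(f"{float(t):.3f} {x:.8f}\n")
        meta["windows"].append({"file": fname, "ref_nm": w.ref, "k_kJmol_nm2": w.k})
    with open(directory / "windows.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_window_set(directory) -> UmbrellaWindowSet:
    directory = Path(directory)
    with open(directory / "windows.json") as fh:
        meta = json.load(fh)
    windows = []
    for entry in meta["windows"]:
        data = np.loadtxt(directory / entry["file"], comments="#", ndmin=2)
        windows.append(UmbrellaWindow(ref=float(entry["ref_nm"]),
                                      k=float(entry["k_kJmol_nm2"]),
                                      samples=data[:, 1]))
    return UmbrellaWindowSet(windows, temperature=float(meta["temperature_K"]))


def write_pull_trace(times, values, path, unit="nm") -> None:
    with open(path, "w") as fh:
        fh.write(f"# pull trace; columns: time_ps value_{unit}\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.6f} {v:.8f}\n")


def read_pull_trace(path):
    data = np.loadtxt(path, comments="#", ndmin=2)
    return data[:, 0], data[:, 1]
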