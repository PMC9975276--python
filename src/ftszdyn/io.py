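"""CSV readers and writers for the four input data kinds.

All formats are plain long-form CSV with a header row:

==================  =====================================================
kind                columns
==================  =====================================================
GTPase traces       time_s, a340, protein_uM, gtp_uM, label
LS trace            time_s, intensity  (one trace per file)
FRAP trace          time_s, bleach, reference, background
sedimentation       label, nucleotide, total, supernatant, pellet
depletion table     label, total_uM, gtp_uM, activity, cc
==================  =====================================================
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .depletion import ReactionSpec
from .errors import InvalidArgumentError
from .frap import FRAPTrace
from .gtpase import AbsorbanceTrace, KineticFit
from .lightscattering import LSTrace
from .sedimentation import SedimentationSample


def write_gtpase_traces(traces: Sequence[AbsorbanceTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_s": tr.time,
                "a340": tr.a340,
                "protein_uM": tr.protein_conc,
                "gtp_uM": tr.gtp_conc,
                "label": tr.label,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gtpase_traces(path: str | Path) -> list[AbsorbanceTrace]:
    df = pd.read_csv(path)
    traces = []
    for label, group in df.groupby("label", sort=False):
        group = group.sort_values("time_s")
        traces.append(
            AbsorbanceTrace(
                time=group["time_s"].to_numpy(float),
                a340=group["a340"].to_numpy(float),
                protein_conc=float(group["protein_uM"].iloc[0]),
                gtp_conc=float(group["gtp_uM"].iloc[0]),
                label=str(label),
            )
        )
    return traces


def write_ls_trace(trace: LSTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "intensity": trace.intensity}).to_csv(
        path, index=False
    )


def read_ls_trace(
    path: str | Path, nucleotide: str = "GTP", label: str = ""
) -> LSTrace:
    df = pd.read_csv(path)
    return LSTrace(
        time=df["time_s"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
        nucleotide=nucleotide,
        label=label or Path(path).stem,
    )


def write_frap_trace(trace: FRAPTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time,
            "bleach": trace.bleach,
            "reference": trace.reference,
            "background": trace.background,
        }
    ).to_csv(path, index=False)


def read_frap_trace(path: str | Path, n_prebleach: int | None = None, label: str = "") -> FRAPTrace:
    """Read a FRAP trace; prebleach frames are those with time_s < 0
    unless ``n_prebleach`` is given explicitly."""
    df = pd.read_csv(path)
    time = df["time_s"].to_numpy(float)
    if n_prebleach is None:
        n_prebleach = int((time < 0).sum())
    if n_prebleach < 1:
        raise InvalidArgumentError(
            "no prebleach frames found (time_s < 0); pass n_prebleach explicitly"
        )
    return FRAPTrace(
        time=time,
        bleach=df["bleach"].to_numpy(float),
        reference=df["reference"].to_numpy(float),
        background=df["background"].to_numpy(float),
        n_prebleach=n_prebleach,
        label=label or Path(path).stem,
    )


def write_sedimentation_samples(
    samples: Sequence[SedimentationSample], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "label": [s.label for s in samples],
            "nucleotide": [s.nucleotide for s in samples],
            "total": [s.density_total for s in samples],
            "supernatant": [s.density_supernatant for s in samples],
            "pellet": [s.density_pellet for s in samples],
        }
    ).to_csv(path, index=False)


def read_sedimentation_samples(path: str | Path) -> list[SedimentationSample]:
    df = pd.read_csv(path)
    samples = []
    for _, row in df.iterrows():
        total = row.get("total")
        samples.append(
            SedimentationSample(
                label=str(row["label"]),
                nucleotide=str(row["nucleotide"]),
                density_supernatant=float(row["supernatant"]),
                density_pellet=float(row["pellet"]),
                density_total=None if total is None or pd.isna(total) else float(total),
            )
        )
    return samples


def read_reaction_table(path: str | Path) -> list[ReactionSpec]:
    """Read a depletion-prediction input table
    (label, total_uM, gtp_uM, activity, cc)."""
    df = pd.read_csv(path)
    specs = []
    for _, row in df.iterrows():
        specs.append(
            ReactionSpec(
                components=((str(row["label"]), float(row["total_uM"])),),
                gtp_conc=float(row["gtp_uM"]),
                kinetics=KineticFit(activity=float(row["activity"]), cc=float(row["cc"])),
                label=str(row["label"]),
            )
        )
    return specs
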