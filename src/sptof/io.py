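"""Containers and delimited-table I/O for acquisition count streams.

An :class:`AcquisitionRun` holds one spICP-TOF-MS acquisition table: one row
per acquisition window, one column per element, integer ion counts (floats are
permitted so that noise-free synthetic runs can carry exact Poisson means).
Tables are written as tab-separated text with ``#``-prefixed metadata header
lines, so every artefact in the pipeline is plain text and self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionRun",
    "read_acquisition_run",
    "write_acquisition_run",
    "read_table",
    "write_table",
]


@dataclass
class AcquisitionRun:
    """Per-acquisition count matrix plus the instrument metadata needed to
    convert counts to masses and event numbers to concentrations.

    Parameters
    ----------
    counts : ndarray, shape (n_acquisitions, n_elements)
        Nonnegative ion counts per acquisition window. Integer-valued under
        counting noise; may be fractional in noise-free simulation mode.
    elements : list of str
        Ordered element labels, one per column.
    t_acq : float
        Acquisition (dwell) time in seconds per window.
    q_sample : float
        Sample uptake flow in mL min^-1.
    dilution_factor : float
        Fold dilution applied to the suspension before measurement (>= 1).
    label : str
        Free-form sample identity (tissue, group, replicate, "blank", ...).
    meta : dict
        Extra metadata carried through to the table header.
    """

    counts: np.ndarray
    elements: list[str]
    t_acq: float
    q_sample: float
    dilution_factor: float = 1.0
    label: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (n_acquisitions x n_elements) array")
        if self.counts.shape[1] != len(self.elements):
            raise ValueError(
                f"counts has {self.counts.shape[1]} columns but "
                f"{len(self.elements)} element labels were given"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.t_acq <= 0:
            raise ValueError("t_acq must be positive")
        if self.q_sample <= 0:
            raise ValueError("q_sample must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def n_acquisitions(self) -> int:
        return self.counts.shape[0]

    @property
    def duration(self) -> float:
        """Total run duration in seconds (n_acquisitions * t_acq)."""
        return self.n_acquisitions * self.t_acq

    def series(self, element: str) -> np.ndarray:
        """Return one element's count stream as a 1-D array."""
        try:
            j = self.elements.index(element)
        except ValueError:
            raise KeyError(f"element {element!r} not in run panel {self.elements}")
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=self.elements)


# ---------------------------------------------------------------------------
# generic '#'-header delimited tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, metadata: dict[str, Any] | None = None) -> None:
    """Write ``df`` as TSV with ``# key: value`` metadata lines on top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_table`; returns (frame, metadata)."""
    path = Path(path)
    metadata: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, metadata


def write_acquisition_run(run: AcquisitionRun, path: str | Path) -> None:
    meta: dict[str, Any] = {
        "t_acq_s": repr(run.t_acq),
        "q_sample_mL_min": repr(run.q_sample),
        "dilution_factor": repr(run.dilution_factor),
        "label": run.label,
    }
    meta.update({str(k): v for k, v in run.meta.items()})
    write_table(run.to_frame(), path, meta)


def read_acquisition_run(path: str | Path) -> AcquisitionRun:
    df, meta = read_table(path)
    known = {"t_acq_s", "q_sample_mL_min", "dilution_factor", "label"}
    extra = {k: v for k, v in meta.items() if k not in known}
    return AcquisitionRun(
        counts=df.to_numpy(dtype=float),
        elements=list(df.columns),
        t_acq=float(meta["t_acq_s"]),
        q_sample=float(meta["q_sample_mL_min"]),
        dilution_factor=float(meta.get("dilution_factor", 1.0)),
        label=meta.get("label", ""),
        meta=extra,
    )
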