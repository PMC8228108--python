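"""Sliding-window primary-sequence property scans.

Local isoelectric point and local aromaticity profiles highlight, from
sequence alone, regions of a disordered protein that carry charge
imbalance (candidate electrostatically stretched linkers) or aromatic
clusters. Each window is scored as a standalone peptide and plotted at
the position of the window center.

The isoelectric point is computed from a Henderson–Hasselbalch charge
model: at pH x, each basic group of pKa k contributes
``+1 / (1 + 10^(x - k))`` and each acidic group ``-1 / (1 + 10^(k - x))``;
the pI is the unique root of the resulting strictly decreasing net
charge. The pKa constants are shipped as an explicit, overridable table
(EMBOSS-style values by default) so the computation is reproducible
down to its constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PkaTable",
    "SequenceProfile",
    "net_charge",
    "peptide_pI",
    "sliding_pI",
    "sliding_aromaticity",
    "read_fasta_sequence",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
AROMATIC = set("FWY")

_DEFAULT_TABLE_PATH = Path(__file__).parent / "data" / "pka_emboss.yaml"


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa constants for the charge model."""

    acidic: dict[str, float]
    basic: dict[str, float]
    n_terminus: float
    c_terminus: float

    def __post_init__(self) -> None:
        values = [*self.acidic.values(), *self.basic.values(), self.n_terminus, self.c_terminus]
        if any(not (0.0 < v < 14.0) for v in values):
            raise ValueError("all pKa values must lie in (0, 14)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PkaTable":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            acidic={k: float(v) for k, v in raw["acidic"].items()},
            basic={k: float(v) for k, v in raw["basic"].items()},
            n_terminus=float(raw["n_terminus"]),
            c_terminus=float(raw["c_terminus"]),
        )

    @classmethod
    def default(cls) -> "PkaTable":
        return cls.from_yaml(_DEFAULT_TABLE_PATH)


@dataclass(frozen=True)
class SequenceProfile:
    """Per-window scalar property indexed by window-center position."""

    property_name: str
    window: int
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        val = np.asarray(self.values, dtype=np.float64)
        if len(pos) != len(val):
            raise ValueError("positions and values differ in length")
        if len(pos) > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, self.property_name: self.values})


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("sequence is empty")
    bad = set(seq.upper()) - STANDARD_AA
    if bad:
        raise ValueError(
            f"nonstandard amino acid letter(s): {', '.join(sorted(bad))}"
        )


def net_charge(seq: str, pH: float, table: PkaTable | None = None) -> float:
    """Net charge (elementary charges) of a free peptide at the given pH.

    Counts ionizable side chains plus one free N-terminus and one free
    C-terminus. Strictly decreasing in pH.
    """
    table = table or PkaTable.default()
    seq = seq.upper()
    _check_sequence(seq)
    pos = 1.0 / (1.0 + 10.0 ** (pH - table.n_terminus))
    neg = 1.0 / (1.0 + 10.0 ** (table.c_terminus - pH))
    for aa in seq:
        if aa in table.basic:
            pos += 1.0 / (1.0 + 10.0 ** (pH - table.basic[aa]))
        elif aa in table.acidic:
            neg += 1.0 / (1.0 + 10.0 ** (table.acidic[aa] - pH))
    return pos - neg


def peptide_pI(seq: str, table: PkaTable | None = None, tol: float = 0.002) -> float:
    """Isoelectric point: root of :func:`net_charge` by bisection.

    With free termini included the net charge is positive at pH 0 and
    negative at pH 14, and strictly monotone, so the root exists and is
    unique; bisection converges to within ``tol`` pH units.
    """
    table = table or PkaTable.default()
    seq = seq.upper()
    _check_sequence(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, table) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _window_centers(residue_start: int, n_windows: int, window: int) -> np.ndarray:
    # center at floor((W-1)/2) offset from the window start (exact for odd W)
    offset = (window - 1) // 2
    return np.arange(residue_start, residue_start + n_windows) + offset


def sliding_pI(
    seq: str,
    window: int = 25,
    table: PkaTable | None = None,
    first_residue_id: int = 1,
) -> SequenceProfile:
    """Sliding-window isoelectric point profile.

    Each contiguous window of ``window`` residues is scored as an
    isolated peptide with free termini; positions are window centers in
    the numbering that starts at ``first_residue_id``.
    """
    table = table or PkaTable.default()
    seq = seq.upper()
    _check_sequence(seq)
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    n_win = len(seq) - window + 1
    values = np.array([peptide_pI(seq[i : i + window], table) for i in range(n_win)])
    return SequenceProfile(
        property_name="pI",
        window=window,
        positions=_window_centers(first_residue_id, n_win, window),
        values=values,
    )


def sliding_aromaticity(
    seq: str, window: int = 25, first_residue_id: int = 1
) -> SequenceProfile:
    """Sliding-window aromatic fraction (Phe, Trp, Tyr count / window size)."""
    seq = seq.upper()
    _check_sequence(seq)
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    indicator = np.array([1.0 if aa in AROMATIC else 0.0 for aa in seq])
    kernel = np.ones(window) / window
    values = np.convolve(indicator, kernel, mode="valid")
    n_win = len(seq) - window + 1
    return SequenceProfile(
        property_name="aromaticity",
        window=window,
        positions=_window_centers(first_residue_id, n_win, window),
        values=values,
    )


def read_fasta_sequence(path: str | Path, record_id: str | None = None) -> str:
    """Read one sequence from a FASTA file (first record by default)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if record_id is None:
        return str(records[0].seq)
    for rec in records:
        if rec.id == record_id:
            return str(rec.seq)
    raise ValueError(f"{path}: record {record_id!r} not found")


def render_profile(profile: SequenceProfile, out: str | Path, dpi: int = 150):
    """Plot a sequence profile as a line over residue position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(profile.positions, profile.values, "-", color="tab:blue")
    ax.set_xlabel("window center (residue)")
    ax.set_ylabel(profile.property_name)
    ax.set_title(f"{profile.property_name}, W = {profile.window}")
    out = Path(out)
    try:
        fig.savefig(out, dpi=dpi)
    finally:
        plt.close(fig)
    return out
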