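"""Secondary-structure timelines and occupancy statistics.

Per-frame secondary-structure assignments come from external tools
(DSSP, cpptraj's secstruct action); this module ingests their tabular
output, normalizes it onto an eight-class alphabet, and computes
per-residue occupancy fractions and helical propensity (the fraction of
frames in any helix class). Assignment itself is never recomputed here.

Eight-class alphabet: H α-helix, G 3₁₀-helix, I π-helix, E extended/β,
B bridge, T turn, S bend, C coil. Unrecognized or blank cells coerce to
coil with a counted warning — long disordered-protein trajectories
routinely contain unassigned residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SSTimeline",
    "SS_CODES",
    "parse_ss_table",
    "write_ss_table",
    "ss_occupancy",
    "helical_propensity",
    "render_ssmap",
]

SS_CODES = ("H", "G", "I", "E", "B", "T", "S", "C")
HELIX_CODES = ("H", "G", "I")

#: cpptraj secstruct integer codes -> eight-class alphabet
#: (0 none, 1 parallel β, 2 antiparallel β, 3 3₁₀, 4 α, 5 π, 6 turn, 7 bend)
CPPTRAJ_CODES = {0: "C", 1: "E", 2: "E", 3: "G", 4: "H", 5: "I", 6: "T", 7: "S"}

#: Default raster palette (bend/bridge default to light grey).
DEFAULT_PALETTE = {
    "H": "#ff9ecf",  # pink
    "G": "#d62728",  # red
    "I": "#10105a",  # dark blue
    "E": "#ffe119",  # yellow
    "B": "#d3d3d3",
    "T": "#7fffff",  # cyan
    "S": "#d3d3d3",
    "C": "#ffffff",  # white
}


@dataclass(frozen=True)
class SSTimeline:
    """Frames × residues categorical secondary-structure codes."""

    residue_ids: np.ndarray
    codes: np.ndarray  # dtype '<U1', shape (n_frames, n_residues)

    def __post_init__(self) -> None:
        rid = np.asarray(self.residue_ids, dtype=np.int64)
        codes = np.asarray(self.codes, dtype="<U1")
        if codes.ndim != 2 or codes.shape[1] != len(rid):
            raise ValueError("codes must be (n_frames, n_residues)")
        if len(rid) > 1 and np.any(np.diff(rid) <= 0):
            raise ValueError("residue_ids must be strictly increasing")
        bad = set(np.unique(codes)) - set(SS_CODES)
        if bad:
            raise ValueError(f"invalid secondary-structure codes: {sorted(bad)}")
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "codes", codes)

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_residues(self) -> int:
        return self.codes.shape[1]


def _coerce_codes(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Map raw one-letter codes to the alphabet; unknowns -> coil."""
    out = np.char.upper(raw.astype("<U1"))
    out[out == ""] = "C"
    out[out == " "] = "C"
    out[out == "-"] = "C"
    known = np.isin(out, SS_CODES)
    n_coerced = int((~known).sum())
    out[~known] = "C"
    return out, n_coerced


def parse_ss_table(path: str | Path, dialect: str = "native") -> SSTimeline:
    """Parse a per-frame secondary-structure table.

    Dialects
    --------
    ``native``
        Long TSV with header ``frame<TAB>residue<TAB>code``; one row per
        (frame, residue) cell.
    ``dssp``
        Wide whitespace table: one row per frame, first column the frame
        index, remaining columns one-letter codes per residue (residue
        ids from a ``#Frame r1 r2 ...`` header, else numbered from 1).
    ``cpptraj``
        Same wide layout with cpptraj secstruct integer codes.

    Unknown or blank cells coerce to coil (C) with a counted warning;
    ragged rows raise with the offending row number.
    """
    path = Path(path)
    if dialect == "native":
        df = pd.read_csv(path, sep="\t", dtype={"frame": int, "residue": int, "code": str})
        expected = {"frame", "residue", "code"}
        if not expected.issubset(df.columns):
            raise ValueError(
                f"{path}: native dialect needs columns {sorted(expected)}, "
                f"found {list(df.columns)}"
            )
        frames = np.sort(df["frame"].unique())
        residues = np.sort(df["residue"].unique())
        pivot = df.pivot_table(
            index="frame", columns="residue", values="code", aggfunc="first"
        ).reindex(index=frames, columns=residues)
        if pivot.isna().any().any():
            n_missing = int(pivot.isna().sum().sum())
            warnings.warn(f"{n_missing} missing (frame, residue) cells coerced to coil")
        raw = pivot.fillna("C").to_numpy(dtype="<U1")
        codes, n_coerced = _coerce_codes(raw)
        if n_coerced:
            warnings.warn(f"{n_coerced} unrecognized codes coerced to coil")
        return SSTimeline(residue_ids=residues, codes=codes)

    if dialect in ("dssp", "cpptraj"):
        rows: list[list[str]] = []
        header_ids: list[int] | None = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.lstrip().startswith("#"):
                    tokens = line.lstrip("# \t").split()
                    if len(tokens) > 1:
                        try:
                            header_ids = [int(t) for t in tokens[1:]]
                        except ValueError:
                            header_ids = None
                    continue
                fields = line.split()
                rows.append(fields[1:])  # first column is the frame index/time
                if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                    raise ValueError(
                        f"{path}:{lineno}: ragged row ({len(rows[-1])} columns, "
                        f"expected {len(rows[0])})"
                    )
        if not rows:
            raise ValueError(f"{path}: no data rows")
        n_res = len(rows[0])
        residue_ids = np.asarray(
            header_ids if header_ids and len(header_ids) == n_res else range(1, n_res + 1)
        )
        if dialect == "cpptraj":
            ints = np.array([[int(float(c)) for c in row] for row in rows])
            unknown = ~np.isin(ints, list(CPPTRAJ_CODES))
            if unknown.any():
                warnings.warn(f"{int(unknown.sum())} unrecognized codes coerced to coil")
            codes = np.vectorize(lambda v: CPPTRAJ_CODES.get(v, "C"))(ints).astype("<U1")
        else:
            raw = np.array(rows, dtype="<U1")
            codes, n_coerced = _coerce_codes(raw)
            if n_coerced:
                warnings.warn(f"{n_coerced} unrecognized codes coerced to coil")
        return SSTimeline(residue_ids=residue_ids, codes=codes)

    raise ValueError(
        f"unsupported dialect {dialect!r}; supported: native, dssp, cpptraj"
    )


def write_ss_table(tl: SSTimeline, path: str | Path) -> Path:
    """Write a timeline in the native long-TSV dialect (lossless)."""
    path = Path(path)
    t, i = np.meshgrid(np.arange(tl.n_frames), np.arange(tl.n_residues), indexing="ij")
    pd.DataFrame(
        {
            "frame": t.ravel(),
            "residue": tl.residue_ids[i.ravel()],
            "code": tl.codes.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def ss_occupancy(tl: SSTimeline) -> pd.DataFrame:
    """Per-residue fraction of frames in each class; rows sum to 1."""
    data = {
        code: (tl.codes == code).mean(axis=0) for code in SS_CODES
    }
    out = pd.DataFrame(data, index=pd.Index(tl.residue_ids, name="residue"))
    return out


def helical_propensity(tl: SSTimeline, first: int | None = None, last: int | None = None) -> pd.Series:
    """Per-residue fraction of frames in any helix class (H, G, I)."""
    first = int(tl.residue_ids[0]) if first is None else first
    last = int(tl.residue_ids[-1]) if last is None else last
    mask = (tl.residue_ids >= first) & (tl.residue_ids <= last)
    if first < tl.residue_ids[0] or last > tl.residue_ids[-1] or not mask.any():
        raise ValueError(
            f"range {first}-{last} outside timeline "
            f"({tl.residue_ids[0]}-{tl.residue_ids[-1]})"
        )
    helix = np.isin(tl.codes[:, mask], HELIX_CODES).mean(axis=0)
    return pd.Series(helix, index=pd.Index(tl.residue_ids[mask], name="residue"), name="helical_propensity")


def render_ssmap(
    timelines: SSTimeline | list[SSTimeline],
    out: str | Path,
    palette: dict[str, str] | None = None,
    dpi: int = 150,
):
    """Residue × time raster of secondary-structure codes.

    Accepts one timeline or several; multiple timelines render
    concatenated along the time axis with separator lines, so that
    independent trajectories can be compared side by side. The palette
    must cover every class present in the data.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if isinstance(timelines, SSTimeline):
        timelines = [timelines]
    if not timelines:
        raise ValueError("need at least one timeline")
    palette = palette or DEFAULT_PALETTE
    present = set()
    for tl in timelines:
        present |= set(np.unique(tl.codes))
    missing = present - set(palette)
    if missing:
        raise ValueError(f"palette missing class(es): {sorted(missing)}")

    code_index = {c: k for k, c in enumerate(SS_CODES)}
    cmap = ListedColormap([palette.get(c, "#ffffff") for c in SS_CODES])
    blocks = []
    for tl in timelines:
        idx = np.vectorize(code_index.__getitem__)(tl.codes)
        blocks.append(idx.T)  # residues × frames
    raster = np.concatenate(blocks, axis=1)

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(raster, aspect="auto", cmap=cmap, vmin=0, vmax=len(SS_CODES) - 1, origin="lower", interpolation="nearest")
    x = 0
    for tl in timelines[:-1]:
        x += tl.n_frames
        ax.axvline(x - 0.5, color="black", linewidth=1.5)
    ax.set_xlabel("frame (concatenated trajectories)")
    ax.set_ylabel("residue index")
    out = Path(out)
    try:
        fig.savefig(out, dpi=dpi)
    finally:
        plt.close(fig)
    return out
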