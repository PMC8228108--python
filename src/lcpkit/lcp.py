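"""Local compaction plots (LCP).

The LCP statistic slices the full intramolecular distance matrix at a
fixed sequence separation: for a window of W residues slid along the
chain one residue at a time, the Cα–Cα distance between the residues at
window positions 1 and W is measured in every frame of the ensemble.
Folded domains give short, frame-invariant distances; flexible linkers
give long, widely scattered ones. Plotting every (window, distance)
point with partial opacity turns point frequency into darkness, so
dominant conformations appear as dense dark traces while rare ones stay
visible as lighter shadows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import ConformationEnsemble

__all__ = [
    "LCPResult",
    "RegionClassification",
    "compute_lcp",
    "lcp_summary",
    "classify_regions",
    "render_lcp",
]

#: Default sliding-window span (inclusive residue count).
DEFAULT_WINDOW = 75
#: Default compact/extended threshold in Å.
COMPACT_MAX = 50.0
EXTENDED_MIN = 50.0


@dataclass(frozen=True)
class LCPResult:
    """Frames × windows distance matrix for a fixed window span.

    ``distances[t, i]`` is the Cα–Cα distance (Å) in frame ``t``
    between the residues at ``window_starts[i]`` and
    ``window_starts[i] + window_span - 1``.
    """

    window_span: int
    window_starts: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.window_starts, dtype=np.int64)
        d = np.asarray(self.distances, dtype=np.float64)
        if d.ndim != 2 or d.shape[1] != len(starts):
            raise ValueError("distances must be (n_frames, n_windows)")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and non-negative")
        object.__setattr__(self, "window_starts", starts)
        object.__setattr__(self, "distances", d)

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]

    @property
    def n_windows(self) -> int:
        return self.distances.shape[1]

    @property
    def window_centers(self) -> np.ndarray:
        """Window positions reported at the center residue (lower median)."""
        return self.window_starts + (self.window_span - 1) // 2

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (frame, window_start, distance)."""
        t, i = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_windows), indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": t.ravel(),
                "window_start": self.window_starts[i.ravel()],
                "distance": self.distances.ravel(),
            }
        )


@dataclass(frozen=True)
class RegionClassification:
    """Per-residue compact/extended/intermediate labels.

    ``window_labels`` classify each window by its across-frame summary
    statistic; ``residue_labels`` map residue id -> label by majority
    vote over the windows covering that residue (ties -> intermediate).
    """

    residue_labels: dict[int, str]
    window_labels: dict[int, str]
    compact_max: float
    extended_min: float
    statistic: str


def compute_lcp(ens: ConformationEnsemble, window: int = DEFAULT_WINDOW) -> LCPResult:
    """Sliding-window intramolecular distances over all frames.

    A window of span ``window`` starting at residue ``i`` measures the
    Euclidean Cα distance between residues ``i`` and ``i + window - 1``
    (inclusive span: ``window=75`` pairs window positions 1 and 75).
    The window slides by one residue until the end of the chain.
    """
    if window < 2:
        raise ValueError(f"window span must be >= 2, got {window}")
    if window > ens.n_residues:
        raise ValueError(
            f"window span {window} exceeds chain length {ens.n_residues}"
        )
    if not ens.is_contiguous:
        gaps = np.nonzero(np.diff(ens.residue_ids) != 1)[0]
        rid = ens.residue_ids
        where = ", ".join(f"{rid[g]}..{rid[g + 1]}" for g in gaps[:5])
        raise ValueError(
            f"residue numbering has gaps ({where}); windows cannot bridge gaps"
        )
    sep = window - 1
    delta = ens.coords[:, sep:, :] - ens.coords[:, : ens.n_residues - sep, :]
    distances = np.linalg.norm(delta, axis=2)
    return LCPResult(
        window_span=window,
        window_starts=ens.residue_ids[: ens.n_residues - sep],
        distances=distances,
    )


def lcp_summary(
    res: LCPResult, percentiles: Sequence[float] = (0.05, 0.5, 0.95)
) -> pd.DataFrame:
    """Per-window summary over frames: mean, sd, min, max, percentiles.

    Percentiles are given as fractions in [0, 1]; an empty list yields
    mean/sd/min/max only. Standard deviation is the population sd (a
    single-frame ensemble has sd 0).
    """
    for p in percentiles:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"percentile {p} outside [0, 1]")
    d = res.distances
    out = pd.DataFrame(
        {
            "window_start": res.window_starts,
            "window_center": res.window_centers,
            "mean": d.mean(axis=0),
            "sd": d.std(axis=0),
            "min": d.min(axis=0),
            "max": d.max(axis=0),
        }
    )
    for p in percentiles:
        out[f"p{100 * p:g}"] = np.quantile(d, p, axis=0)
    return out


def classify_regions(
    res: LCPResult,
    compact_max: float = COMPACT_MAX,
    extended_min: float = EXTENDED_MIN,
    statistic: str = "median",
) -> RegionClassification:
    """Label residues compact / extended / intermediate.

    Each window's across-frame summary (median by default, robust to
    multimodal conformational mixtures) is compared to the thresholds:
    below ``compact_max`` -> compact, at or above ``extended_min`` ->
    extended, otherwise intermediate. Residues take the majority label
    of the windows covering them; ties go to intermediate.
    """
    if compact_max <= 0 or extended_min <= 0:
        raise ValueError("thresholds must be positive")
    if compact_max > extended_min:
        raise ValueError(
            f"compact_max ({compact_max}) must be <= extended_min ({extended_min})"
        )
    if statistic == "median":
        summary = np.median(res.distances, axis=0)
    elif statistic == "mean":
        summary = res.distances.mean(axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    window_labels: dict[int, str] = {}
    for start, value in zip(res.window_starts, summary):
        if value < compact_max:
            label = "compact"
        elif value >= extended_min:
            label = "extended"
        else:
            label = "intermediate"
        window_labels[int(start)] = label

    starts = res.window_starts
    W = res.window_span
    first_res, last_res = int(starts[0]), int(starts[-1] + W - 1)
    residue_labels: dict[int, str] = {}
    for rid in range(first_res, last_res + 1):
        covering = [
            window_labels[int(s)] for s in starts if s <= rid <= s + W - 1
        ]
        counts = {lab: covering.count(lab) for lab in set(covering)}
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        residue_labels[rid] = winners[0] if len(winners) == 1 else "intermediate"
    return RegionClassification(
        residue_labels=residue_labels,
        window_labels=window_labels,
        compact_max=compact_max,
        extended_min=extended_min,
        statistic=statistic,
    )


def render_lcp(
    res: LCPResult,
    out: str | Path,
    mode: str = "overplot",
    alpha: float = 0.02,
    position: str = "start",
    reference_frame: int | None = None,
    dpi: int = 150,
):
    """Render a density-aware LCP figure.

    ``overplot`` mode draws every (window, distance) point at the given
    opacity so that frequent distances accumulate darkness; ``density``
    mode draws a 2-D histogram. ``position`` selects whether windows are
    plotted at their start or center residue. ``reference_frame``
    overlays a single frame's trace in red (e.g. a starting structure).
    Returns the written path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if res.n_windows == 0:
        raise ValueError("empty LCP result")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if position == "start":
        x = res.window_starts
    elif position == "center":
        x = res.window_centers
    else:
        raise ValueError(f"position must be 'start' or 'center', got {position!r}")

    fig, ax = plt.subplots(figsize=(8, 4))
    if mode == "overplot":
        xs = np.tile(x, res.n_frames)
        ax.plot(
            xs,
            res.distances.ravel(),
            ".",
            color="black",
            alpha=alpha,
            markersize=2,
            rasterized=True,
        )
    elif mode == "density":
        xs = np.tile(x, res.n_frames)
        ax.hist2d(
            xs,
            res.distances.ravel(),
            bins=(len(x), 80),
            cmap="Greys",
        )
    else:
        raise ValueError(f"mode must be 'overplot' or 'density', got {mode!r}")
    if reference_frame is not None:
        ax.plot(x, res.distances[reference_frame], "-", color="red", linewidth=1.0)
    ax.set_xlabel(f"window {position} (residue)")
    ax.set_ylabel("distance (Å)")
    ax.set_title(f"Local compaction plot, W = {res.window_span}")
    out = Path(out)
    try:
        fig.savefig(out, dpi=dpi)
    finally:
        plt.close(fig)
    return out


def write_lcp_outputs(
    res: LCPResult,
    out_dir: str | Path,
    classification: RegionClassification | None = None,
    position: str = "start",
) -> dict[str, Path]:
    """Write the LCP matrix, per-window summary and metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "lcp_matrix.tsv",
        "summary": out_dir / "lcp_summary.tsv",
        "metadata": out_dir / "lcp_metadata.json",
    }
    res.to_frame().to_csv(paths["matrix"], sep="\t", index=False)
    lcp_summary(res).to_csv(paths["summary"], sep="\t", index=False)
    meta = {
        "window_span": res.window_span,
        "n_frames": res.n_frames,
        "n_windows": res.n_windows,
        "position_convention": position,
    }
    if classification is not None:
        meta["thresholds"] = {
            "compact_max": classification.compact_max,
            "extended_min": classification.extended_min,
            "statistic": classification.statistic,
        }
        labels = pd.DataFrame(
            sorted(classification.residue_labels.items()),
            columns=["residue", "label"],
        )
        paths["labels"] = out_dir / "region_labels.tsv"
        labels.to_csv(paths["labels"], sep="\t", index=False)
    paths["metadata"].write_text(json.dumps(meta, indent=2))
    return paths
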