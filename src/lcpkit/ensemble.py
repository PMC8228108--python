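"""Core ensemble container for Cα-based conformational analysis.

A :class:`ConformationEnsemble` holds per-frame Cα coordinates for a
contiguous stretch of protein sequence, keyed by the author's residue
numbering so that downstream analyses (window positions, segment
selections) can be addressed in the same coordinates used in the
literature on the protein under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConformationEnsemble"]


@dataclass(frozen=True)
class ConformationEnsemble:
    """Per-frame Cα coordinates for a contiguous residue range.

    Parameters
    ----------
    residue_ids
        Ordered residue numbers (author numbering, 1-based). Strictly
        increasing; one entry per residue.
    sequence
        One-letter amino acid string aligned to ``residue_ids``.
    coords
        Array of shape ``(n_frames, n_residues, 3)`` with Cα positions
        in Ångström.
    """

    residue_ids: np.ndarray
    sequence: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        rid = np.asarray(self.residue_ids, dtype=np.int64)
        xyz = np.asarray(self.coords, dtype=np.float64)
        if xyz.ndim != 3 or xyz.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_residues, 3), got {xyz.shape}"
            )
        if xyz.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if not (len(rid) == len(self.sequence) == xyz.shape[1]):
            raise ValueError(
                "residue_ids, sequence and per-frame coordinates disagree in length: "
                f"{len(rid)}, {len(self.sequence)}, {xyz.shape[1]}"
            )
        if len(rid) and np.any(np.diff(rid) <= 0):
            raise ValueError("residue_ids must be strictly increasing")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates contain non-finite values")
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "coords", xyz)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    @property
    def is_contiguous(self) -> bool:
        """True when residue numbering has no gaps."""
        return self.n_residues < 2 or bool(np.all(np.diff(self.residue_ids) == 1))

    def index_of(self, residue_id: int) -> int:
        """Position of ``residue_id`` in the ensemble, or raise KeyError."""
        hits = np.nonzero(self.residue_ids == residue_id)[0]
        if len(hits) == 0:
            lo, hi = self.residue_ids[0], self.residue_ids[-1]
            raise KeyError(
                f"residue {residue_id} not in ensemble (available range {lo}-{hi})"
            )
        return int(hits[0])

    def select_segment(self, first: int, last: int) -> "ConformationEnsemble":
        """Restrict the ensemble to residues ``first``..``last`` inclusive.

        Numbering is preserved, so selections compose: selecting
        ``[a, b]`` then ``[c, d]`` (with ``a <= c <= d <= b``) equals
        selecting ``[c, d]`` directly.
        """
        if first > last:
            raise ValueError(f"first ({first}) must be <= last ({last})")
        i = self.index_of(first)
        j = self.index_of(last)
        return ConformationEnsemble(
            residue_ids=self.residue_ids[i : j + 1],
            sequence=self.sequence[i : j + 1],
            coords=self.coords[:, i : j + 1, :],
        )


def select_segment(ens: ConformationEnsemble, first: int, last: int) -> ConformationEnsemble:
    """Functional alias for :meth:`ConformationEnsemble.select_segment`."""
    return ens.select_segment(first, last)
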