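"""Reading and writing structural ensembles.

Multi-model PDB files are handled with Biopython (which preserves
author residue numbering, occupancies and alternate locations), while
topology + trajectory pairs in MD formats (DCD, XTC, ... against PDB or
PRMTOP topologies) go through mdtraj. Either route produces the same
Cα-only :class:`~lcpkit.ensemble.ConformationEnsemble`.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio import BiopythonWarning
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.Atom import Atom
from Bio.PDB.Chain import Chain
from Bio.PDB.Model import Model
from Bio.PDB.Residue import Residue
from Bio.PDB.Structure import Structure
from Bio.SeqUtils import seq1, seq3

from .ensemble import ConformationEnsemble

__all__ = ["load_pdb_ensemble", "load_trajectory", "write_pdb_ensemble"]


def _protein_residues(chain) -> list:
    """Standard-residue (non-hetero) amino acids of a Biopython chain."""
    out = []
    for res in chain:
        if res.id[0] != " ":
            continue
        if seq1(res.get_resname(), undef_code="X") == "X" and res.get_resname() not in (
            "MSE",
        ):
            # unknown residue name: keep only if it has a CA (protein-like)
            if "CA" not in res:
                continue
        out.append(res)
    return out


def _pick_ca(res) -> Atom:
    """The Cα atom of a residue; highest-occupancy altloc wins.

    Biopython's disordered-atom machinery already selects the
    highest-occupancy alternate location (ties resolved by altloc
    identifier order on input).
    """
    atom = res["CA"]
    if atom.is_disordered():
        atom = atom.selected_child
    return atom


def load_pdb_ensemble(path: str | Path, chain: str | None = None) -> ConformationEnsemble:
    """Load a (multi-model) PDB file as a Cα ensemble.

    Each MODEL record becomes one frame; a single-structure file yields
    a one-frame ensemble. By default the first chain containing protein
    residues is used; pass ``chain`` to select another.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonWarning)
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")

    def chain_of(model) -> Chain:
        chains = {c.id: c for c in model}
        if chain is not None:
            if chain not in chains:
                raise ValueError(
                    f"{path}: chain {chain!r} not present (has {sorted(chains)})"
                )
            return chains[chain]
        for c in model:
            if _protein_residues(c):
                return c
        raise ValueError(f"{path}: no protein chain with Cα atoms found")

    ref_chain = chain_of(models[0])
    ref_residues = _protein_residues(ref_chain)
    if not ref_residues:
        raise ValueError(f"{path}: chain {ref_chain.id!r} has no protein residues")
    ref_ids = [r.id[1] for r in ref_residues]

    frames = []
    for model in models:
        c = chain_of(model)
        residues = _protein_residues(c)
        ids = [r.id[1] for r in residues]
        if ids != ref_ids:
            raise ValueError(
                f"{path}: residue set differs between MODEL {models[0].id + 1} "
                f"and MODEL {model.id + 1}"
            )
        xyz = np.empty((len(residues), 3))
        for k, res in enumerate(residues):
            if "CA" not in res:
                raise ValueError(
                    f"{path}: residue {res.get_resname()} {res.id[1]} "
                    f"(chain {c.id}) has no Cα atom"
                )
            xyz[k] = _pick_ca(res).coord
        frames.append(xyz)

    sequence = "".join(seq1(r.get_resname(), undef_code="X") for r in ref_residues)
    return ConformationEnsemble(
        residue_ids=np.asarray(ref_ids), sequence=sequence, coords=np.stack(frames)
    )


def load_trajectory(
    topology: str | Path,
    trajectory: str | Path,
    stride: int | None = None,
    first_residue_id: int | None = None,
) -> ConformationEnsemble:
    """Load a topology + trajectory pair as a Cα ensemble.

    Frames come in file order; ``stride`` keeps every n-th frame (a
    stride longer than the trajectory keeps the first frame only).
    ``first_residue_id`` renumbers residues when the topology carries no
    author numbering (e.g. PRMTOP files, which always start at 1).
    """
    import mdtraj as md

    try:
        traj = md.load(str(trajectory), top=str(topology), stride=stride)
    except (OSError, IOError) as exc:
        raise ValueError(
            f"could not read trajectory {trajectory} with topology {topology}: {exc}"
        ) from exc
    ca = traj.topology.select("protein and name CA")
    if len(ca) == 0:
        raise ValueError(f"{topology}: no protein Cα atoms found")
    traj = traj.atom_slice(ca)
    residues = list(traj.topology.residues)
    ids = [r.resSeq for r in residues]
    if first_residue_id is not None:
        ids = [first_residue_id + k for k in range(len(residues))]
    sequence = "".join((r.code or "X") for r in residues)
    return ConformationEnsemble(
        residue_ids=np.asarray(ids),
        sequence=sequence,
        coords=np.asarray(traj.xyz, dtype=np.float64) * 10.0,  # nm -> Å
    )


def write_pdb_ensemble(ens: ConformationEnsemble, path: str | Path, chain: str = "A") -> Path:
    """Write an ensemble as a multi-model, Cα-only PDB file."""
    path = Path(path)
    structure = Structure(path.stem)
    for t in range(ens.n_frames):
        model = Model(t)
        ch = Chain(chain)
        for k, rid in enumerate(ens.residue_ids):
            aa = ens.sequence[k]
            resname = seq3(aa).upper() if aa != "X" else "UNK"
            res = Residue((" ", int(rid), " "), resname, "")
            res.add(
                Atom(
                    "CA",
                    np.asarray(ens.coords[t, k], dtype=np.float32),
                    1.0,
                    1.0,
                    " ",
                    " CA ",
                    k + 1,
                    element="C",
                )
            )
            ch.add(res)
        model.add(ch)
        structure.add(model)
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(path))
    return path
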