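"""GRO / XTC trajectory I/O for synthetic and simulated membrane frames.

Frames are written as (optionally concatenated) GRO blocks with distinct
residue names per particle class — upper-leaflet beads ``UMB``, lower
``LMB``, peptides ``PEP`` — and the box on the final line of each block.
Concatenated multi-frame GRO files are parsed natively here (the standard
trajectory readers treat GRO as single-frame); single-frame parses are
cross-checked against MDAnalysis in the test suite, and XTC trajectories go
through MDAnalysis.

All public functions speak nm (the GRO native unit); MDAnalysis's internal
angstroms are converted at the boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .synthetic import MembraneFrame, PeptideRecord

__all__ = [
    "write_gro",
    "read_gro",
    "write_xtc",
    "read_trajectory",
    "UPPER_RESNAME",
    "LOWER_RESNAME",
    "PEPTIDE_RESNAME",
]

UPPER_RESNAME = "UMB"
LOWER_RESNAME = "LMB"
PEPTIDE_RESNAME = "PEP"
_BEAD_NAME = "PO4"
_PEPTIDE_NAME = "BB"


def _format_block(frame: MembraneFrame, title: str) -> str:
    lines = [title]
    n = len(frame.upper_beads) + len(frame.lower_beads) + len(frame.peptides)
    lines.append(f"{n:5d}")
    idx = 0

    def emit(resname, atomname, pos):
        nonlocal idx
        idx += 1
        resid = idx % 100000
        lines.append(
            f"{resid:5d}{resname:<5s}{atomname:>5s}{idx % 100000:5d}"
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
        )

    for pos in frame.upper_beads:
        emit(UPPER_RESNAME, _BEAD_NAME, pos)
    for pos in frame.lower_beads:
        emit(LOWER_RESNAME, _BEAD_NAME, pos)
    for pep in frame.peptides:
        emit(PEPTIDE_RESNAME, _PEPTIDE_NAME, pep.position)
    lines.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    return "\n".join(lines) + "\n"


def write_gro(frames, path, *, title: str = "curvsense synthetic buckled membrane") -> None:
    """Write one frame or a list of frames as a (concatenated) GRO file."""
    if isinstance(frames, MembraneFrame):
        frames = [frames]
    with open(path, "w") as fh:
        for i, frame in enumerate(frames):
            fh.write(_format_block(frame, f"{title} frame {i}"))


def _parse_block(lines) -> MembraneFrame:
    natoms = int(lines[1])
    upper, lower, peptides = [], [], []
    for raw in lines[2 : 2 + natoms]:
        resname = raw[5:10].strip()
        pos = np.array([float(raw[20:28]), float(raw[28:36]), float(raw[36:44])])
        if resname == UPPER_RESNAME:
            upper.append(pos)
        elif resname == LOWER_RESNAME:
            lower.append(pos)
        else:
            peptides.append(pos)
    box_fields = lines[2 + natoms].split()
    box = tuple(float(v) for v in box_fields[:3])
    return MembraneFrame(
        upper_beads=np.array(upper).reshape(-1, 3),
        lower_beads=np.array(lower).reshape(-1, 3),
        peptides=[
            PeptideRecord(label=f"PEP{i + 1}", leaflet=None, position=p)
            for i, p in enumerate(peptides)
        ],
        box=box,
    )


def read_gro(path) -> list[MembraneFrame]:
    """Read a single-frame or concatenated GRO file into MembraneFrames.

    Particle classes are recognized by residue name (UMB/LMB = leaflet
    beads, anything else = peptide).  Peptide leaflet assignments are not
    stored in GRO and are left to the analysis (nearest fitted surface);
    labels are regenerated positionally as PEP1, PEP2, ...
    """
    text = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        natoms = int(text[i + 1])
        frames.append(_parse_block(text[i : i + natoms + 3]))
        i += natoms + 3
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return frames


def _frames_to_universe(frames):
    import MDAnalysis as mda

    first = frames[0]
    n_up, n_lo, n_pep = len(first.upper_beads), len(first.lower_beads), len(first.peptides)
    n = n_up + n_lo + n_pep
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n), trajectory=True)
    u.add_TopologyAttr("resnames",
                       [UPPER_RESNAME] * n_up + [LOWER_RESNAME] * n_lo + [PEPTIDE_RESNAME] * n_pep)
    u.add_TopologyAttr("names",
                       [_BEAD_NAME] * (n_up + n_lo) + [_PEPTIDE_NAME] * n_pep)
    return u


def _frame_positions_nm(frame):
    parts = [frame.upper_beads, frame.lower_beads]
    if frame.peptides:
        parts.append(np.array([p.position for p in frame.peptides]))
    return np.concatenate(parts, axis=0)


def write_xtc(frames, xtc_path, gro_path=None) -> None:
    """Write frames as an XTC trajectory (plus a GRO topology if given)."""
    import MDAnalysis as mda

    if gro_path is not None:
        write_gro(frames[0], gro_path)
    u = _frames_to_universe(frames)
    n = len(u.atoms)
    with mda.Writer(str(xtc_path), n) as writer:
        for frame in frames:
            u.atoms.positions = _frame_positions_nm(frame) * 10.0  # nm -> A
            u.dimensions = [frame.box[0] * 10, frame.box[1] * 10, frame.box[2] * 10,
                            90.0, 90.0, 90.0]
            writer.write(u.atoms)


def read_trajectory(
    topology,
    trajectory=None,
    *,
    upper_sel: str = f"resname {UPPER_RESNAME}",
    lower_sel: str = f"resname {LOWER_RESNAME}",
    peptide_sel: str = f"resname {PEPTIDE_RESNAME}",
) -> list[MembraneFrame]:
    """Read frames via MDAnalysis selections (GRO topology + e.g. XTC).

    Each peptide residue contributes one point: the centre of mass of its
    selected particles (a single bead in synthetic data).  Without a
    trajectory file a GRO is read natively, supporting concatenated frames.
    """
    if trajectory is None:
        return read_gro(topology)

    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(trajectory))
    upper = u.select_atoms(upper_sel)
    lower = u.select_atoms(lower_sel)
    peptide = u.select_atoms(peptide_sel)
    if len(peptide) == 0:
        raise ValueError(f"peptide selection {peptide_sel!r} matched no atoms")
    if len(upper) == 0 or len(lower) == 0:
        raise ValueError("leaflet selections matched no atoms")
    frames = []
    for ts in u.trajectory:
        box = tuple(ts.dimensions[:3] / 10.0)
        peps = []
        for i, res in enumerate(peptide.residues):
            com = res.atoms.intersection(peptide).positions.mean(axis=0) / 10.0
            peps.append(PeptideRecord(label=f"PEP{i + 1}", leaflet=None, position=com))
        frames.append(
            MembraneFrame(
                upper_beads=upper.positions / 10.0,
                lower_beads=lower.positions / 10.0,
                peptides=peps,
                box=box,
            )
        )
    return frames
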