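"""Wimley-White hydropathy, idealized LS peptides, and helical wheels.

Mean hydrophobicity is the arithmetic mean of per-residue water-to-membrane
partitioning free energies; with the packaged Wimley-White interfacial
scale, negative values indicate favorable partitioning into the bilayer
interface.  The LS peptide family consists of 21-residue leucine/serine
amphipathic helices labelled LSX, with X serines placed so that they form a
single contiguous polar arc on the ideal helical wheel (100 degrees per
residue); decreasing the serine count makes the family monotonically more
hydrophobic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "HydrophobicityScale",
    "PeptideSequence",
    "load_scale",
    "interface_scale",
    "octanol_scale",
    "mean_hydrophobicity",
    "build_ls_sequence",
    "helical_wheel",
    "read_fasta",
    "write_fasta",
    "plot_helical_wheel",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: ideal alpha-helix rotation per residue (degrees)
WHEEL_STEP_DEG = 100.0

LS_LENGTH = 21


@dataclass(frozen=True)
class HydrophobicityScale:
    """Per-residue partitioning free energies (kcal/mol)."""

    name: str
    values: dict  # one-letter residue -> kcal/mol
    sign_convention: str = "negative = favorable partitioning"
    citation: str = ""

    def __post_init__(self):
        missing = STANDARD_RESIDUES - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name} missing residues: {sorted(missing)}")


@dataclass(frozen=True)
class PeptideSequence:
    label: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residues in {self.label}: {sorted(bad)}")

    @property
    def n_ser(self) -> int:
        return self.residues.count("S")

    def __len__(self) -> int:
        return len(self.residues)


def load_scale(path) -> HydrophobicityScale:
    """Read a scale CSV with '#' header metadata lines (name, units, ...)."""
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            else:
                rows.append(line)
    values = {}
    for rec in csv.DictReader(rows):
        values[rec["residue"].strip()] = float(rec["delta_g"])
    return HydrophobicityScale(
        name=meta.get("name", "unnamed"),
        values=values,
        sign_convention=meta.get("sign_convention", "negative = favorable partitioning"),
        citation=meta.get("citation", ""),
    )


def _packaged_scale(fname: str) -> HydrophobicityScale:
    with resources.as_file(resources.files("curvsense.data") / fname) as path:
        return load_scale(path)


def interface_scale() -> HydrophobicityScale:
    """The packaged Wimley-White interfacial scale (package default)."""
    return _packaged_scale("wimley_white_interface.csv")


def octanol_scale() -> HydrophobicityScale:
    """The packaged Wimley-White octanol scale."""
    return _packaged_scale("wimley_white_octanol.csv")


def mean_hydrophobicity(seq, scale: HydrophobicityScale | None = None) -> float:
    """Mean per-residue partitioning free energy (kcal/mol per residue)."""
    residues = seq.residues if isinstance(seq, PeptideSequence) else str(seq)
    if len(residues) == 0:
        raise ValueError("empty sequence")
    scale = scale or interface_scale()
    try:
        return sum(scale.values[r] for r in residues) / len(residues)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in scale {scale.name}") from None


def helical_wheel(seq) -> list[tuple[int, str, float]]:
    """(position, residue, wheel angle in degrees) for an ideal alpha helix.

    Positions are 1-based; angle_i = 100*(i-1) mod 360.
    """
    residues = seq.residues if isinstance(seq, PeptideSequence) else str(seq)
    if len(residues) == 0:
        raise ValueError("empty sequence")
    return [
        (i + 1, r, (WHEEL_STEP_DEG * i) % 360.0) for i, r in enumerate(residues)
    ]


def _angular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def build_ls_sequence(n_ser: int, polar_axis: float = 180.0) -> PeptideSequence:
    """Idealized 21-residue L/S amphipathic helix with ``n_ser`` serines.

    Serines occupy the positions whose helical-wheel angles lie nearest the
    polar-face axis (default 180 degrees), producing a single contiguous
    polar arc on the wheel; ties are broken by sequence position, so the
    construction is deterministic.  These sequences are idealized stand-ins,
    not experimentally characterized peptides.
    """
    if not 0 <= n_ser <= LS_LENGTH:
        raise ValueError(f"n_ser must be in [0, {LS_LENGTH}], got {n_ser}")
    angles = [(WHEEL_STEP_DEG * i) % 360.0 for i in range(LS_LENGTH)]
    order = sorted(range(LS_LENGTH), key=lambda i: (_angular_distance(angles[i], polar_axis), i))
    polar = set(order[:n_ser])
    residues = "".join("S" if i in polar else "L" for i in range(LS_LENGTH))
    return PeptideSequence(label=f"LS{n_ser}", residues=residues)


# -- FASTA I/O -------------------------------------------------------------
def read_fasta(path) -> list[PeptideSequence]:
    from Bio import SeqIO

    return [
        PeptideSequence(label=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s.residues), id=s.label, description="") for s in sequences
    ]
    seqio_write(records, str(path), "fasta")


def plot_helical_wheel(seq, ax=None, scale: HydrophobicityScale | None = None):
    """Minimal helical-wheel plot; hydrophobic residues filled dark."""
    import math

    import matplotlib.pyplot as plt

    scale = scale or interface_scale()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    label = seq.label if isinstance(seq, PeptideSequence) else "peptide"
    for pos, res, ang in helical_wheel(seq):
        r = 1.0 + 0.04 * ((pos - 1) // 18)  # spiral out after a full turn
        x = r * math.cos(math.radians(ang))
        y = r * math.sin(math.radians(ang))
        hydrophobic = scale.values.get(res, 0.0) < 0
        ax.scatter(
            [x], [y], s=380, c="#444444" if hydrophobic else "#e8e8e8",
            edgecolors="k", zorder=2,
        )
        ax.text(x, y, res, ha="center", va="center",
                color="w" if hydrophobic else "k", zorder=3)
    ax.set_xlim(-1.45, 1.45)
    ax.set_ylim(-1.45, 1.45)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(label)
    return ax
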