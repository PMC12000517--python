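"""Polyglutamine fibril-core width arithmetic.

In the amyloid core of huntingtin exon-1 fibrils the polyQ tract forms
beta-strands with ~3.5 Angstrom (0.35 nm) rise per residue.  A tract of
Q residues folded into ``s`` strands connected by turns of ``t``
residues each contributes strands of (Q - (s-1) t)/s residues, so the
core width is

    width = (Q - (s - 1) * t) / s * spacing        [nm]

and a fibril built from ``f`` laterally associated filaments is ``f``
times wider (filament packing is additive along the strand direction).
Examples: Q32 as one extended strand gives 11.2 nm; folded into a
beta-hairpin (two strands, 4-residue turn) it gives 14 residues per
strand and 4.9 nm.

The default 4-residue turn is the canonical beta-turn; beta-arc or
other turn motifs that consume a different residue count are expressed
through ``turn_len``.  Widths refer to the rigid polyQ core only — the
flexible flanking domains (the "fuzzy coat") are excluded, matching
what negative-stain TEM measures for these fibrils.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = ["GeometryModel", "ArchitectureCandidate", "strand_length",
           "core_width", "fibril_width", "enumerate_architectures",
           "RESIDUE_SPACING_NM"]

#: beta-strand rise per residue, nm (~3.5 Angstrom)
RESIDUE_SPACING_NM = 0.35

#: residues consumed by a canonical beta-turn
DEFAULT_TURN_LEN = 4


@dataclass(frozen=True)
class GeometryModel:
    """One candidate polyQ core architecture."""

    polyq_len: int
    spacing: float = RESIDUE_SPACING_NM  # nm per residue
    strands_per_monomer: int = 1
    turn_len: int = DEFAULT_TURN_LEN  # residues per turn
    n_filaments: int = 1

    def __post_init__(self) -> None:
        if self.polyq_len < 1:
            raise ValueError("polyq_len must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.strands_per_monomer < 1:
            raise ValueError("strands_per_monomer must be >= 1")
        if self.turn_len < 0:
            raise ValueError("turn_len must be >= 0")
        if self.n_filaments < 1:
            raise ValueError("n_filaments must be >= 1")
        needed = self.strands_per_monomer + (self.strands_per_monomer - 1) * self.turn_len
        if self.polyq_len < needed:
            raise ValueError(
                f"polyq_len={self.polyq_len} too short for "
                f"{self.strands_per_monomer} strands with {self.turn_len}-residue "
                f"turns (needs >= {needed})")

    @property
    def residues_per_strand(self) -> float:
        s, t = self.strands_per_monomer, self.turn_len
        return (self.polyq_len - (s - 1) * t) / s


@dataclass(frozen=True)
class ArchitectureCandidate:
    """An architecture compatible with an observed width, with its error."""

    strands_per_monomer: int
    n_filaments: int
    predicted_width: float  # nm
    relative_error: float  # |predicted - observed| / observed


def strand_length(n_res: int, spacing: float = RESIDUE_SPACING_NM) -> float:
    """Length in nm of an extended beta-strand of ``n_res`` residues."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    return n_res * spacing


def core_width(gm: GeometryModel) -> float:
    """Width of the polyQ core of a single filament, nm."""
    return gm.residues_per_strand * gm.spacing


def fibril_width(core_w: float, n_filaments: int) -> float:
    """Width of a fibril of ``n_filaments`` laterally stacked filaments."""
    if core_w <= 0:
        raise ValueError("core width must be positive")
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    return n_filaments * core_w


def enumerate_architectures(polyq_len: int, observed_width: float,
                            tol: float = 0.15, max_strands: int = 3,
                            max_filaments: int = 3,
                            spacing: float = RESIDUE_SPACING_NM,
                            turn_len: int = DEFAULT_TURN_LEN,
                            ) -> list[ArchitectureCandidate]:
    """All (strand count, filament count) architectures whose predicted
    fibril width falls within ``tol`` (relative) of ``observed_width``,
    ranked by agreement.

    Architectures geometrically impossible for the tract length (too
    many strands for the residues available) are skipped; an empty list
    means no candidate fits.
    """
    if observed_width <= 0:
        raise ValueError("observed_width must be positive")
    if not 0 < tol <= 0.5:
        raise ValueError("tol must be in (0, 0.5]")
    out: list[ArchitectureCandidate] = []
    for s, f in product(range(1, max_strands + 1), range(1, max_filaments + 1)):
        try:
            gm = GeometryModel(polyq_len=polyq_len, spacing=spacing,
                               strands_per_monomer=s, turn_len=turn_len,
                               n_filaments=f)
        except ValueError:
            continue
        w = fibril_width(core_width(gm), f)
        err = abs(w - observed_width) / observed_width
        if err <= tol:
            out.append(ArchitectureCandidate(s, f, w, err))
    out.sort(key=lambda c: (c.relative_error, c.strands_per_monomer, c.n_filaments))
    return out
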