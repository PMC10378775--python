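"""Sequences, modifications, and mass algebra for the amyloid-beta metal-binding domain.

The N-terminal 1-16 fragment of amyloid-beta (Abeta16) chelates Zn(II) through its
acidic and histidine residues.  This module holds the peptide representation shared
by every analysis stage: variant bookkeeping (wild type, the Taiwan D7H mutation,
isoaspartate-7, phospho-Ser8, English H6R, alanine scans), C-terminal amidation,
monoisotopic mass arithmetic, and the notion of a chelation-capable position.

Residue numbering is 1-based amyloid-beta numbering throughout the package; the free
N-terminal amine is addressed as pseudo-position 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

#: Canonical human amyloid-beta 1-16 (from the APP precursor).  Every residue label
#: used in the analyses (D1, E3, H6, D7/H7, S8, Y10, E11, H13, H14) maps onto it.
ABETA16_SEQUENCE = "DAEFRHDSGYEVHHQK"

#: Monoisotopic residue masses (Da), from the pyteomics residue table.
RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

WATER_MONO = 18.0105646863
PROTON_MONO = 1.00727646688
H_MONO = 1.00782503207
N_MONO = 14.0030740048
O_MONO = 15.9949146221
#: Monoisotopic mass of the most abundant zinc isotope.
ZN_MONO = 63.9291422
#: C-terminal amidation replaces the acid -OH with -NH2.
AMIDE_DELTA = (N_MONO + 2 * H_MONO) - (O_MONO + H_MONO)  # -0.9840156 Da
#: Each bound zinc displaces two protons ([M + nZn - 2nH + zH]z+).
ZN_ADDUCT_DELTA = ZN_MONO - 2 * H_MONO

VARIANTS = ("WT", "D7H", "isoD7", "pS8", "H6R", "custom")

#: Residue types that can coordinate a zinc ion.  Gly and Ala side chains cannot.
DEFAULT_CAPABLE_SET = frozenset("DEHCMY")

#: Molar extinction coefficient of Tyr10 at 276 nm, M^-1 cm^-1.
TYR_EXTINCTION_276 = 1450.0


class PeptideError(ValueError):
    """Raised for invalid sequences, variants, or modifications."""


@dataclass(frozen=True)
class Peptide:
    """A (possibly modified) amyloid-beta fragment.

    Attributes
    ----------
    residues : str
        One-letter residue codes, position 1 first.
    numbering_offset : int
        Number added to the 1-based index to obtain amyloid-beta numbering
        (0 for fragments starting at residue 1).
    variant : str
        One of ``WT, D7H, isoD7, pS8, H6R, custom``.
    point_mutations : mapping position -> one-letter replacement applied on top of
        the variant (used for the alanine scan mutants, e.g. ``{11: "A"}``).
    c_terminal_amide : bool
        All peptides in this study are C-terminally amidated; kept configurable.
    n_terminal_free : bool
        Whether the alpha-amine is free (counts as chelation pseudo-position 0).
    iso_asp_positions : tuple of positions flagged as isoaspartate (isobaric).
    """

    residues: str
    numbering_offset: int = 0
    variant: str = "WT"
    point_mutations: Mapping[int, str] = field(default_factory=dict)
    c_terminal_amide: bool = True
    n_terminal_free: bool = True
    iso_asp_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise PeptideError("empty sequence")
        for aa in self.residues:
            if aa not in RESIDUE_MASS:
                raise PeptideError(f"unknown residue code {aa!r}")
        if self.variant not in VARIANTS:
            raise PeptideError(f"unknown variant {self.variant!r}")
        for pos in self.point_mutations:
            self._check_position(pos)
        for pos in self.iso_asp_positions:
            self._check_position(pos)
            if self.residue_at(pos) != "D":
                raise PeptideError(
                    f"isoaspartate flag at position {pos} requires Asp, "
                    f"found {self.residue_at(pos)!r}"
                )
        if self.variant == "D7H" and self.residue_at(7) != "H":
            raise PeptideError("variant D7H requires His at position 7")
        if self.variant == "isoD7" and 7 not in self.iso_asp_positions:
            raise PeptideError("variant isoD7 requires the isoAsp flag at position 7")

    # -- positions ---------------------------------------------------------

    def _check_position(self, pos: int) -> None:
        if not 1 <= pos - self.numbering_offset <= len(self.residues):
            raise PeptideError(f"position {pos} outside the sequence")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> range:
        """All residue positions in amyloid-beta numbering."""
        first = 1 + self.numbering_offset
        return range(first, first + len(self.residues))

    def residue_at(self, pos: int) -> str:
        self._check_position(pos)
        return self.residues[pos - self.numbering_offset - 1]

    # -- masses ------------------------------------------------------------

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in Da (isoAsp is isobaric and changes nothing)."""
        m = sum(RESIDUE_MASS[aa] for aa in self.residues) + WATER_MONO
        if self.c_terminal_amide:
            m += AMIDE_DELTA
        return m


def build_peptide(
    sequence: str,
    variant: str = "WT",
    options: Mapping | None = None,
) -> Peptide:
    """Validate and build a :class:`Peptide`.

    ``variant="D7H"`` applied to the canonical sequence substitutes Asp7 -> His;
    ``variant="isoD7"`` flags position 7 as isoaspartate (elemental composition
    unchanged).  Extra point mutations (e.g. the alanine scan) are passed through
    ``options={"mutations": {11: "A"}}``.
    """
    opts = dict(options or {})
    offset = int(opts.pop("numbering_offset", 0))
    c_amide = bool(opts.pop("c_term_amide", True))
    n_free = bool(opts.pop("n_term_free", True))
    mutations = dict(opts.pop("mutations", {}))
    if opts:
        raise PeptideError(f"unknown options: {sorted(opts)}")
    if not sequence:
        raise PeptideError("empty sequence")

    seq = list(sequence.upper())
    iso_positions: tuple[int, ...] = ()
    if variant == "D7H":
        idx = 7 - offset - 1
        if not 0 <= idx < len(seq):
            raise PeptideError("D7H variant requires the sequence to span position 7")
        if seq[idx] not in ("D", "H"):
            raise PeptideError("D7H variant requires Asp (or His) at position 7")
        seq[idx] = "H"
    elif variant == "isoD7":
        idx = 7 - offset - 1
        if not 0 <= idx < len(seq) or seq[idx] != "D":
            raise PeptideError("isoD7 flag requires Asp at position 7")
        iso_positions = (7,)
    elif variant == "pS8":
        if seq[8 - offset - 1] != "S":
            raise PeptideError("pS8 variant requires Ser at position 8")
    elif variant == "H6R":
        idx = 6 - offset - 1
        if seq[idx] not in ("H", "R"):
            raise PeptideError("H6R variant requires His at position 6")
        seq[idx] = "R"

    for pos, repl in mutations.items():
        repl = repl.upper()
        if repl not in RESIDUE_MASS:
            raise PeptideError(f"unknown replacement residue {repl!r}")
        idx = pos - offset - 1
        if not 0 <= idx < len(seq):
            raise PeptideError(f"mutation position {pos} outside the sequence")
        seq[idx] = repl

    return Peptide(
        residues="".join(seq),
        numbering_offset=offset,
        variant=variant,
        point_mutations=mutations,
        c_terminal_amide=c_amide,
        n_terminal_free=n_free,
        iso_asp_positions=iso_positions,
    )


def abeta16(variant: str = "WT", options: Mapping | None = None) -> Peptide:
    """The canonical metal-binding domain, optionally with a variant applied."""
    return build_peptide(ABETA16_SEQUENCE, variant, options)


def monoisotopic_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass of the peptide in Da."""
    return p.monoisotopic_mass


def chelation_capable_positions(
    p: Peptide,
    capable_set: Iterable[str] | None = None,
    include_n_terminus: bool = True,
) -> set[int]:
    """Positions whose residue type can coordinate Zn(II).

    The default capable set is {Asp, Glu, His, Cys, Met, Tyr}; the free N-terminal
    amine is reported as pseudo-position 0 when present and enabled.  Gly and Ala
    can never chelate.
    """
    cap = frozenset(capable_set) if capable_set is not None else DEFAULT_CAPABLE_SET
    if cap & {"G", "A"}:
        raise PeptideError("Gly and Ala cannot be chelation-capable")
    out = {pos for pos in p.positions if p.residue_at(pos) in cap}
    if include_n_terminus and p.n_terminal_free:
        out.add(p.numbering_offset)
    return out


def concentration_from_absorbance(
    a276: float,
    path_cm: float = 1.0,
    extinction: float = TYR_EXTINCTION_276,
) -> float:
    """Beer-Lambert peptide concentration (M) from Tyr absorbance at 276 nm."""
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    if a276 < 0:
        raise ValueError("absorbance must be non-negative")
    return a276 / (extinction * path_cm)


# -- FASTA I/O -------------------------------------------------------------


def read_fasta(handle_or_path, variant: str = "WT", options: Mapping | None = None) -> list[Peptide]:
    """Read peptides from FASTA.  Variant/modification flags come from ``options``
    (keys ``variant:``, ``mutations:``, ``c_term_amide:`` may also be embedded in
    the description, e.g. ``>pep variant:D7H c_term_amide:true``)."""
    from Bio import SeqIO

    peptides = []
    for rec in SeqIO.parse(handle_or_path, "fasta"):
        opts = dict(options or {})
        var = variant
        for token in rec.description.split()[1:]:
            if ":" not in token:
                continue
            key, value = token.split(":", 1)
            if key == "variant":
                var = value
            elif key == "c_term_amide":
                opts["c_term_amide"] = value.lower() in ("1", "true", "yes")
            elif key == "mutations":
                muts = {}
                for item in value.split(","):
                    muts[int(item[:-1])] = item[-1]
                opts["mutations"] = muts
        peptides.append(build_peptide(str(rec.seq), var, opts))
    return peptides


def write_fasta(peptides: Iterable[Peptide], handle_or_path) -> None:
    close = False
    if isinstance(handle_or_path, (str, bytes)):
        handle = open(handle_or_path, "w")
        close = True
    else:
        handle = handle_or_path
    try:
        for i, p in enumerate(peptides):
            flags = [f"variant:{p.variant}", f"c_term_amide:{str(p.c_terminal_amide).lower()}"]
            if p.point_mutations:
                muts = ",".join(f"{pos}{aa}" for pos, aa in sorted(p.point_mutations.items()))
                flags.append(f"mutations:{muts}")
            handle.write(f">pep{i + 1} {' '.join(flags)}\n{p.residues}\n")
    finally:
        if close:
            handle.close()
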