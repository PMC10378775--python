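"""Residue-pair contact census over multi-chain trajectories.

A dimer (or larger) trajectory is scanned for frames in which the side chains of
two residues on different chains approach within a distance cutoff (default
4.5 A, strict less-than, minimum over heavy side-chain atoms).  The census feeds
a steric-exclusion step that selects the zinc-mediated interfaces an oligomer
can actually use: residue pairs never seen in contact are dropped, pairs that
cannot co-chelate in the same molecule are removed, and the survivors are named
as symmetric interfaces around the primary E11/H14 zinc bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ContactConfig",
    "ContactStats",
    "InterfaceSpec",
    "ExclusionRules",
    "load_trajectory",
    "pair_contact_frames",
    "interface_census",
    "feasible_interfaces",
    "census_table",
    "DEFAULT_RULES",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA"}


class ContactError(ValueError):
    pass


@dataclass(frozen=True)
class ContactConfig:
    """Distance cutoff in Angstrom and the atom scope of the minimum distance."""

    cutoff: float = 4.5
    atom_scope: str = "sidechain"  # or "heavy"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ContactError("cutoff must be positive")
        if self.atom_scope not in ("sidechain", "heavy"):
            raise ContactError("atom_scope must be 'sidechain' or 'heavy'")


@dataclass(frozen=True)
class ContactStats:
    pair: tuple[tuple[str, int], tuple[str, int]]
    frames_in_contact: int
    frames_total: int

    @property
    def fraction(self) -> float:
        return self.frames_in_contact / self.frames_total


@dataclass(frozen=True)
class InterfaceSpec:
    """A zinc-mediated intermolecular interface: residue pair on subunit A,
    residue pair on subunit B, one shared zinc (e.g. E11/H14:ZN:E11/H14)."""

    pair_a: tuple[str, str]
    pair_b: tuple[str, str]
    affinity_class: str = "low"

    @property
    def name(self) -> str:
        return f"{self.pair_a[0]}/{self.pair_a[1]}:ZN:{self.pair_b[0]}/{self.pair_b[1]}"


class Trajectory:
    """Thin wrapper over an MDAnalysis Universe with chain/residue indexing in
    1-based amyloid-beta numbering."""

    def __init__(self, universe) -> None:
        self.universe = universe
        if len(universe.trajectory) < 1:
            raise ContactError("trajectory has no frames")
        self._atom_counts = universe.atoms.n_atoms

    @property
    def frame_count(self) -> int:
        return len(self.universe.trajectory)

    @property
    def chains(self) -> list[str]:
        seen = []
        for cid in self.universe.atoms.chainIDs:
            if cid not in seen:
                seen.append(cid)
        return seen

    def residue_atoms(self, chain: str, resid: int, scope: str = "sidechain"):
        sel = self.universe.select_atoms(f"chainID {chain} and resid {resid}")
        if sel.n_atoms == 0:
            raise ContactError(f"no atoms for chain {chain} residue {resid}")
        atoms = sel.select_atoms("not name H*")
        if scope == "sidechain":
            side = atoms.select_atoms(
                "not name " + " ".join(sorted(_BACKBONE))
            )
            # Gly has no heavy side-chain atoms: fall back to CA
            atoms = side if side.n_atoms else atoms.select_atoms("name CA")
        return atoms

    def chain_sequence(self, chain: str) -> dict[int, str]:
        from MDAnalysis.lib.util import convert_aa_code

        out = {}
        sel = self.universe.select_atoms(f"chainID {chain}")
        for res in sel.residues:
            try:
                out[int(res.resid)] = convert_aa_code(res.resname)
            except ValueError:
                out[int(res.resid)] = "X"
        return out


def load_trajectory(
    topology,
    coordinates=None,
    expected_sequences: dict[str, str] | None = None,
) -> Trajectory:
    """Load a multi-model PDB (standalone) or a topology + trajectory pair.

    ``expected_sequences`` maps chain id -> one-letter sequence and, when given,
    is validated against the file.
    """
    import MDAnalysis as mda
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if coordinates is None:
            u = mda.Universe(str(topology))
        else:
            coords = (
                [str(c) for c in coordinates]
                if isinstance(coordinates, (list, tuple))
                else str(coordinates)
            )
            u = mda.Universe(str(topology), coords)
    traj = Trajectory(u)
    if expected_sequences:
        for chain, seq in expected_sequences.items():
            found = traj.chain_sequence(chain)
            got = "".join(found[r] for r in sorted(found))
            if got != seq:
                raise ContactError(
                    f"chain {chain} sequence mismatch: expected {seq}, found {got}"
                )
    return traj


def _min_dist_per_frame(traj: Trajectory, atoms_a, atoms_b) -> np.ndarray:
    from MDAnalysis.analysis.distances import distance_array

    out = np.empty(traj.frame_count)
    for k, _ in enumerate(traj.universe.trajectory):
        out[k] = distance_array(atoms_a.positions, atoms_b.positions).min()
    return out


def pair_contact_frames(
    traj: Trajectory,
    a: tuple[str, int],
    b: tuple[str, int],
    cfg: ContactConfig = ContactConfig(),
) -> ContactStats:
    """Count frames where the minimum in-scope distance between two residues is
    strictly below the cutoff."""
    atoms_a = traj.residue_atoms(*a, scope=cfg.atom_scope)
    atoms_b = traj.residue_atoms(*b, scope=cfg.atom_scope)
    dmin = _min_dist_per_frame(traj, atoms_a, atoms_b)
    return ContactStats(
        pair=(a, b),
        frames_in_contact=int(np.sum(dmin < cfg.cutoff)),
        frames_total=traj.frame_count,
    )


def interface_census(
    traj: Trajectory,
    candidate_pairs: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    cfg: ContactConfig = ContactConfig(),
) -> list[ContactStats]:
    """One ContactStats per candidate residue pair, in input order."""
    if not candidate_pairs:
        raise ContactError("candidate pair list is empty")
    return [pair_contact_frames(traj, a, b, cfg) for a, b in candidate_pairs]


def census_table(census: Iterable[ContactStats], cfg: ContactConfig = ContactConfig()) -> pd.DataFrame:
    rows = [
        {
            "chain_a": s.pair[0][0],
            "res_a": s.pair[0][1],
            "chain_b": s.pair[1][0],
            "res_b": s.pair[1][1],
            "frames_in_contact": s.frames_in_contact,
            "frames_total": s.frames_total,
            "fraction": s.fraction,
            "cutoff_A": cfg.cutoff,
            "atom_scope": cfg.atom_scope,
        }
        for s in census
    ]
    return pd.DataFrame(rows)


# -- steric exclusion / feasible interfaces --------------------------------


@dataclass(frozen=True)
class ExclusionRules:
    """Same-molecule feasibility rules for candidate chelation pairs.

    ``forbidden_pairs``: residue pairs that can never jointly chelate a zinc in
    one molecule (H6/H13 is sterically impossible).  ``mutually_exclusive``:
    groups of pairs that cannot all exist concurrently in the same molecule;
    when more than one member of a group shows contact evidence, the whole
    group is discarded (E3/H7 with H6/H13).  ``anchor`` is the primary
    high-affinity interface, always present; ``high_affinity`` labels pairs
    classed as high-affinity.
    """

    forbidden_pairs: tuple[frozenset, ...] = (frozenset({"H6", "H13"}),)
    mutually_exclusive: tuple[tuple[frozenset, ...], ...] = (
        (frozenset({"E3", "H7"}), frozenset({"H6", "H13"})),
    )
    anchor: tuple[str, str] = ("E11", "H14")
    high_affinity: tuple[tuple[str, str], ...] = (("E11", "H14"),)


DEFAULT_RULES = ExclusionRules()


def feasible_interfaces(
    census: Iterable[ContactStats],
    rules: ExclusionRules = DEFAULT_RULES,
    residue_names: dict[int, str] | None = None,
) -> list[InterfaceSpec]:
    """Select feasible symmetric zinc interfaces from a contact census.

    1. residue pairs with zero contact frames are dropped;
    2. forbidden pairs and violated mutual-exclusion groups are dropped;
    3. each surviving pair (plus the anchor) becomes a symmetric interface,
       with the affinity class from the rules.
    """
    stats = list(census)
    if stats and len({s.frames_total for s in stats}) > 1:
        raise ContactError("census mixes different frame totals")

    def pair_key(s: ContactStats) -> frozenset:
        names = []
        for chain, res in s.pair:
            if residue_names and res in residue_names:
                names.append(residue_names[res])
            else:
                names.append(str(res))
        return frozenset(names)

    observed: dict[frozenset, int] = {}
    for s in stats:
        key = pair_key(s)
        observed[key] = observed.get(key, 0) + s.frames_in_contact

    with_contact = {k for k, frames in observed.items() if frames > 0}
    surviving = set(with_contact)
    # exclusion groups judged on observed evidence, before forbidden removal
    for group in rules.mutually_exclusive:
        present = [g for g in group if g in with_contact]
        if len(present) > 1:
            surviving -= set(present)
    surviving -= set(rules.forbidden_pairs)

    def order(key: frozenset) -> tuple[str, str]:
        def rank(name: str) -> int:
            try:
                return int("".join(c for c in name if c.isdigit()))
            except ValueError:
                return 0

        return tuple(sorted(key, key=rank))  # type: ignore[return-value]

    out = []
    if stats:
        anchor = rules.anchor
        out.append(
            InterfaceSpec(
                anchor,
                anchor,
                "high" if anchor in rules.high_affinity else "low",
            )
        )
    for key in sorted(surviving, key=lambda k: order(k)):
        pair = order(key)
        if pair == rules.anchor:
            continue
        out.append(
            InterfaceSpec(
                pair, pair, "high" if pair in rules.high_affinity else "low"
            )
        )
    return out
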