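"""Combinatorics of zinc-bridged oligomer assembly.

Each peptide subunit exposes variant-specific interface sites (intramolecular
residue pairs that can jointly chelate a shared zinc): wild type has E11/H14 and
E3/H6; the Taiwan D7H mutant adds H7/H13; the isoAsp7 isoform replaces E3/H6
with H6/H13.  A zinc bridge joins one free site on each of two subunits and
carries exactly one zinc ion.  Assemblies are site-labelled multigraphs; the
named topologies reproduce the published dimer, tetramers, octamer, dodecamer
and the heterotrimers (central modified peptide flanked by two wild-type
peptides attached through their E11/H14 sites).

Growth bookkeeping follows two structural rules observed in the modelling:

* the E11/H14 dimer is the polymerization unit, so a lateral *seed* is a pair
  of same-type free sites on the two subunits of one E11/H14 dimer (an incoming
  dimer docks with two bridges at once);
* a subunit whose E11/H14 site is already zinc-bridged cannot re-form its
  intramolecular H7/H13 (or H6/H13) pair to recruit a *new* subunit — those
  interfaces only arise concurrently with E11/H14 dimerization, which is why a
  tetramer closed through H7/H13 cannot keep polymerizing through it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Subunit",
    "ZincBridge",
    "Assembly",
    "AssemblyRules",
    "make_subunit",
    "new_assembly",
    "add_bridge",
    "replace_variant",
    "build_named_assembly",
    "free_seed_count",
    "can_extend",
    "VARIANT_SITES",
    "NAMED_TOPOLOGIES",
]

EVHH = "E11/H14"
E3H6 = "E3/H6"
H7H13 = "H7/H13"
H6H13 = "H6/H13"

#: Interface-site complement per variant.
VARIANT_SITES: dict[str, tuple[str, ...]] = {
    "WT": (EVHH, E3H6),
    "D7H": (EVHH, E3H6, H7H13),
    "isoD7": (EVHH, H6H13),
}

MODIFIED_VARIANTS = ("D7H", "isoD7")

#: Site-type compatibility: the three homotypic interfaces plus the heterotypic
#: pairings the heterotrimers use (E11/H14 against the modified-variant sites).
_HOMOTYPIC = (
    frozenset({EVHH}),
    frozenset({E3H6}),
    frozenset({H7H13}),
)
_HETEROTYPIC = (
    frozenset({EVHH, H7H13}),
    frozenset({EVHH, H6H13}),
)

#: Sites that require an intramolecular pair geometry incompatible with an
#: occupied E11/H14 when recruiting a fresh subunit.
_CONFORMATION_GATED = {H7H13, H6H13}


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class AssemblyRules:
    """Bridge-legality switches.

    ``strict_homotypic`` restricts bridges to same-type pairings of the three
    homotypic interfaces.  ``recruitment`` is the seeding rule for mixed
    assemblies: a wild-type subunit only engages its E11/H14 site, and only
    with a modified partner (wild type alone stays monomeric with zinc).
    """

    strict_homotypic: bool = False
    recruitment: bool = True

    def compatible(self, site_a: str, site_b: str) -> bool:
        key = frozenset({site_a, site_b})
        if key in _HOMOTYPIC:
            return True
        return (not self.strict_homotypic) and key in _HETEROTYPIC


DEFAULT_RULES = AssemblyRules()


@dataclass(frozen=True)
class Subunit:
    index: int
    variant: str

    @property
    def sites(self) -> tuple[str, ...]:
        return VARIANT_SITES[self.variant]

    @property
    def is_modified(self) -> bool:
        return self.variant in MODIFIED_VARIANTS


@dataclass(frozen=True)
class ZincBridge:
    """One shared zinc joining a site on each of two distinct subunits."""

    endpoint_a: tuple[int, str]
    endpoint_b: tuple[int, str]

    zinc_count: int = 1

    def touches(self, subunit: int, site: str) -> bool:
        return (subunit, site) in (self.endpoint_a, self.endpoint_b)


@dataclass
class Assembly:
    """An immutable-by-convention graph of subunits joined by zinc bridges."""

    subunits: list[Subunit] = field(default_factory=list)
    bridges: list[ZincBridge] = field(default_factory=list)
    rules: AssemblyRules = DEFAULT_RULES
    topology_name: str = ""
    orientation_notes: dict[str, str] = field(default_factory=dict)

    # -- inspection -------------------------------------------------------

    @property
    def zinc_total(self) -> int:
        return sum(b.zinc_count for b in self.bridges)

    def site_occupied(self, subunit: int, site: str) -> bool:
        return any(b.touches(subunit, site) for b in self.bridges)

    def free_sites(self) -> list[tuple[int, str]]:
        return [
            (su.index, site)
            for su in self.subunits
            for site in su.sites
            if not self.site_occupied(su.index, site)
        ]

    def variants_present(self) -> set[str]:
        return {su.variant for su in self.subunits}

    def evhh_dimer_pairs(self) -> list[tuple[int, int]]:
        """Subunit pairs joined by an E11/H14:ZN:E11/H14 bridge."""
        out = []
        for b in self.bridges:
            if b.endpoint_a[1] == EVHH and b.endpoint_b[1] == EVHH:
                out.append((b.endpoint_a[0], b.endpoint_b[0]))
        return out

    def to_graph(self):
        """The assembly as a networkx multigraph (nodes carry variants, edges
        carry the site labels of their endpoints)."""
        import networkx as nx

        g = nx.MultiGraph()
        for su in self.subunits:
            g.add_node(su.index, variant=su.variant)
        for b in self.bridges:
            g.add_edge(
                b.endpoint_a[0],
                b.endpoint_b[0],
                site_a=b.endpoint_a[1],
                site_b=b.endpoint_b[1],
            )
        return g

    def is_connected(self) -> bool:
        import networkx as nx

        g = self.to_graph()
        return g.number_of_nodes() > 0 and nx.is_connected(g)

    # -- growth legality --------------------------------------------------

    def _subunit(self, index: int) -> Subunit:
        for su in self.subunits:
            if su.index == index:
                return su
        raise AssemblyError(f"no subunit {index}")

    def bridge_legal(
        self, e1: tuple[int, str], e2: tuple[int, str], _new_partner: Subunit | None = None
    ) -> str | None:
        """None if the bridge is legal, else the reason it is not."""
        (i1, s1), (i2, s2) = e1, e2
        if i1 == i2:
            return "self-bridge"
        su1, su2 = self._subunit(i1), self._subunit(i2)
        if s1 not in su1.sites:
            return f"subunit {i1} ({su1.variant}) has no site {s1}"
        if s2 not in su2.sites:
            return f"subunit {i2} ({su2.variant}) has no site {s2}"
        if self.site_occupied(i1, s1) or self.site_occupied(i2, s2):
            return "site already occupied"
        if not self.rules.compatible(s1, s2):
            return f"incompatible site types {s1} / {s2}"
        if self.rules.recruitment:
            for su, site, partner in ((su1, s1, su2), (su2, s2, su1)):
                if not su.is_modified and su.variant == "WT":
                    if site != EVHH:
                        return "wild-type subunits engage only their E11/H14 site"
                    if not partner.is_modified:
                        return "wild-type subunits bridge only modified partners"
        return None

    # -- serialization ----------------------------------------------------

    def to_text(self) -> str:
        lines = [f"# assembly {self.topology_name or 'unnamed'}"]
        for su in self.subunits:
            lines.append(f"subunit {su.index} {su.variant}")
        for b in self.bridges:
            (i1, s1), (i2, s2) = b.endpoint_a, b.endpoint_b
            lines.append(f"bridge {i1}:{s1} {i2}:{s2}")
        for key, note in sorted(self.orientation_notes.items()):
            lines.append(f"note {key} {note}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, rules: AssemblyRules = DEFAULT_RULES) -> "Assembly":
        asm = cls(rules=rules)
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, *rest = line.split(maxsplit=1)
            if kind == "subunit":
                idx, variant = rest[0].split()
                asm.subunits.append(Subunit(int(idx), variant))
            elif kind == "bridge":
                p1, p2 = rest[0].split()
                i1, s1 = p1.split(":", 1)
                i2, s2 = p2.split(":", 1)
                asm = add_bridge(asm, (int(i1), s1), (int(i2), s2))
            elif kind == "note":
                key, note = rest[0].split(maxsplit=1)
                asm.orientation_notes[key] = note
        return asm


# -- construction ----------------------------------------------------------


def make_subunit(variant: str, index: int = 0) -> Subunit:
    """A fresh subunit with all of the variant's interface sites free."""
    if variant not in VARIANT_SITES:
        raise AssemblyError(f"unknown variant {variant!r}")
    return Subunit(index, variant)


def new_assembly(
    variants: Sequence[str], rules: AssemblyRules = DEFAULT_RULES, name: str = ""
) -> Assembly:
    subunits = [make_subunit(v, i) for i, v in enumerate(variants)]
    return Assembly(subunits=subunits, rules=rules, topology_name=name)


def add_bridge(a: Assembly, e1: tuple[int, str], e2: tuple[int, str]) -> Assembly:
    """A new assembly with one more zinc bridge; raises on illegal bridges."""
    reason = a.bridge_legal(e1, e2)
    if reason is not None:
        raise AssemblyError(reason)
    return Assembly(
        subunits=list(a.subunits),
        bridges=list(a.bridges) + [ZincBridge(e1, e2)],
        rules=a.rules,
        topology_name=a.topology_name,
        orientation_notes=dict(a.orientation_notes),
    )


def replace_variant(a: Assembly, index: int, variant: str) -> Assembly:
    """Swap a subunit's variant, keeping all bridges (the new variant must still
    expose every bridged site)."""
    if variant not in VARIANT_SITES:
        raise AssemblyError(f"unknown variant {variant!r}")
    subunits = []
    for su in a.subunits:
        if su.index == index:
            for b in a.bridges:
                for ep in (b.endpoint_a, b.endpoint_b):
                    if ep[0] == index and ep[1] not in VARIANT_SITES[variant]:
                        raise AssemblyError(
                            f"variant {variant} lacks bridged site {ep[1]}"
                        )
            su = Subunit(index, variant)
        subunits.append(su)
    return Assembly(
        subunits=subunits,
        bridges=list(a.bridges),
        rules=a.rules,
        topology_name=a.topology_name,
        orientation_notes=dict(a.orientation_notes),
    )


# -- named topologies ------------------------------------------------------

NAMED_TOPOLOGIES = (
    "dimer_EVHH",
    "tetramer_E3H6",
    "tetramer_H7H13",
    "octamer",
    "dodecamer",
    "heterotrimer_D7H",
    "heterotrimer_isoD7",
)


def _tetramer(second: str) -> Assembly:
    a = new_assembly(["D7H"] * 4, name=f"tetramer_{second.replace('/', '')}")
    a = add_bridge(a, (0, EVHH), (1, EVHH))
    a = add_bridge(a, (2, EVHH), (3, EVHH))
    a = add_bridge(a, (0, second), (3, second))
    a = add_bridge(a, (1, second), (2, second))
    a.orientation_notes["arrangement"] = "antiparallel"
    return a


def build_named_assembly(name: str) -> Assembly:
    """Construct one of the published oligomer topologies.

    * ``dimer_EVHH``: two D7H peptides, one E11/H14:ZN:E11/H14 bridge;
    * ``tetramer_E3H6`` / ``tetramer_H7H13``: two E11/H14 dimers joined by two
      bridges of the second interface type;
    * ``octamer``: four E11/H14 dimers chained by alternating H7/H13 and E3/H6
      interfaces;
    * ``dodecamer``: three tetramer blocks (H7/H13-closed, E3/H6-closed,
      H7/H13-closed) chained through one E3/H6 and one H7/H13 inter-block
      interface;
    * ``heterotrimer_D7H`` / ``heterotrimer_isoD7``: a central modified peptide
      whose E11/H14 and second coordination centre (H7/H13 or H6/H13) each hold
      a zinc shared with the E11/H14 site of a flanking wild-type peptide.
    """
    if name == "dimer_EVHH":
        a = new_assembly(["D7H", "D7H"], name=name)
        return add_bridge(a, (0, EVHH), (1, EVHH))

    if name == "tetramer_E3H6":
        return _tetramer(E3H6)
    if name == "tetramer_H7H13":
        return _tetramer(H7H13)

    if name == "octamer":
        a = new_assembly(["D7H"] * 8, name=name)
        for d in range(4):
            a = add_bridge(a, (2 * d, EVHH), (2 * d + 1, EVHH))
        for left, site in ((1, H7H13), (3, E3H6), (5, H7H13)):
            a = add_bridge(a, (left, site), (left + 1, site))
        a.orientation_notes["arrangement"] = "antiparallel"
        return a

    if name == "dodecamer":
        a = new_assembly(["D7H"] * 12, name=name)
        for d in range(6):
            a = add_bridge(a, (2 * d, EVHH), (2 * d + 1, EVHH))
        # three tetramer blocks: (d1,d2) and (d5,d6) closed through H7/H13,
        # (d3,d4) closed through E3/H6; blocks chained through E3/H6 and H7/H13
        a = add_bridge(a, (1, H7H13), (2, H7H13))  # block 1 internal
        a = add_bridge(a, (3, E3H6), (4, E3H6))  # block 1 - block 2
        a = add_bridge(a, (5, E3H6), (6, E3H6))  # block 2 internal
        a = add_bridge(a, (7, H7H13), (8, H7H13))  # block 2 - block 3
        a = add_bridge(a, (9, H7H13), (10, H7H13))  # block 3 internal
        a.orientation_notes["blocks"] = "H7/H13, E3/H6, H7/H13"
        return a

    if name in ("heterotrimer_D7H", "heterotrimer_isoD7"):
        central = "D7H" if name.endswith("D7H") else "isoD7"
        second = H7H13 if central == "D7H" else H6H13
        a = new_assembly(["WT", central, "WT"], name=name)
        a = add_bridge(a, (0, EVHH), (1, EVHH))
        a = add_bridge(a, (2, EVHH), (1, second))
        a.orientation_notes["arrangement"] = (
            "parallel" if central == "D7H" else "antiparallel flank at H6/H13"
        )
        return a

    raise AssemblyError(f"unknown topology {name!r}")


# -- seeds and extension ---------------------------------------------------


def _site_available_for_recruitment(a: Assembly, subunit: int, site: str) -> bool:
    """Free, and not conformationally gated by an occupied E11/H14."""
    if a.site_occupied(subunit, site):
        return False
    if site in _CONFORMATION_GATED and a.site_occupied(subunit, EVHH):
        return False
    return True


def _legal_partner_sites(a: Assembly, subunit: int, site: str, variant: str) -> list[str]:
    """Sites of a fresh ``variant`` subunit that could legally bridge
    (subunit, site); evaluated with a probe subunit appended."""
    probe = Assembly(
        subunits=list(a.subunits) + [make_subunit(variant, max((s.index for s in a.subunits), default=-1) + 1)],
        bridges=list(a.bridges),
        rules=a.rules,
    )
    fresh = probe.subunits[-1]
    return [
        t
        for t in fresh.sites
        if probe.bridge_legal((subunit, site), (fresh.index, t)) is None
    ]


def free_seed_count(
    a: Assembly,
    variant_pool: Iterable[str] | None = None,
    unit: str = "dimer",
) -> int:
    """Number of polymerization seeds on an assembly.

    With the default ``unit="dimer"`` a seed is an attachment slot for a fresh
    E11/H14 dimer: a pair of free, conformationally available sites of the same
    non-E11/H14 type on the two subunits of one existing E11/H14 dimer, legally
    bridgeable from a pool variant.  ``unit="monomer"`` counts free available
    sites that could legally accept a single bridge from a fresh pool subunit.

    ``variant_pool`` defaults to the variants already present in the assembly.
    """
    if unit not in ("dimer", "monomer"):
        raise AssemblyError("unit must be 'dimer' or 'monomer'")
    pool = set(variant_pool) if variant_pool is not None else a.variants_present()
    if not a.subunits or not pool:
        return 0

    if unit == "monomer":
        count = 0
        for su_idx, site in a.free_sites():
            if not _site_available_for_recruitment(a, su_idx, site):
                continue
            if any(_legal_partner_sites(a, su_idx, site, v) for v in pool):
                count += 1
        return count

    count = 0
    for i1, i2 in a.evhh_dimer_pairs():
        su1 = a._subunit(i1)
        su2 = a._subunit(i2)
        for site in set(su1.sites) & set(su2.sites) - {EVHH}:
            if not (
                _site_available_for_recruitment(a, i1, site)
                and _site_available_for_recruitment(a, i2, site)
            ):
                continue
            # the incoming dimer presents the same site type on both subunits
            if any(
                site in _legal_partner_sites(a, i1, site, v)
                and site in _legal_partner_sites(a, i2, site, v)
                for v in pool
            ):
                count += 1
    return count


def can_extend(a: Assembly, variant_pool: Iterable[str]) -> bool:
    """Whether any legal extension exists, by dimer docking or single-bridge
    monomer recruitment, given the pool of available fresh-subunit variants."""
    if not a.subunits:
        return False
    pool = set(variant_pool)
    return (
        free_seed_count(a, pool, unit="dimer") > 0
        or free_seed_count(a, pool, unit="monomer") > 0
    )
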