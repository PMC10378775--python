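import itertools

import numpy as np
import pytest

from abzinc.assembly import (
    EVHH,
    E3H6,
    H7H13,
    H6H13,
    Assembly,
    AssemblyError,
    AssemblyRules,
    add_bridge,
    build_named_assembly,
    can_extend,
    free_seed_count,
    make_subunit,
    new_assembly,
    replace_variant,
    NAMED_TOPOLOGIES,
    VARIANT_SITES,
)


class TestSubunits:
    def test_variant_site_complements(self):
        assert len(make_subunit("WT").sites) == 2
        assert len(make_subunit("D7H").sites) == 3
        assert set(make_subunit("isoD7").sites) == {EVHH, H6H13}

    def test_unknown_variant_rejected(self):
        with pytest.raises(AssemblyError):
            make_subunit("D7N")


class TestBridges:
    def test_evhh_dimer_carries_one_zinc(self):
        a = new_assembly(["D7H", "D7H"])
        a = add_bridge(a, (0, EVHH), (1, EVHH))
        assert a.zinc_total == 1 and len(a.bridges) == 1

    def test_occupied_site_rejected(self):
        a = build_named_assembly("dimer_EVHH")
        with pytest.raises(AssemblyError):
            add_bridge(a, (0, EVHH), (1, EVHH))

    def test_self_bridge_rejected(self):
        a = new_assembly(["D7H", "D7H"])
        with pytest.raises(AssemblyError):
            add_bridge(a, (0, EVHH), (0, E3H6))

    def test_incompatible_site_types_rejected(self):
        a = new_assembly(["D7H", "D7H"])
        with pytest.raises(AssemblyError):
            add_bridge(a, (0, E3H6), (1, H7H13))

    def test_wild_type_evhh_accepts_modified_heterotypic_bridge(self):
        a = new_assembly(["WT", "D7H"])
        a = add_bridge(a, (0, EVHH), (1, H7H13))
        assert a.zinc_total == 1

    def test_wild_type_pair_blocked_under_recruitment(self):
        a = new_assembly(["WT", "WT"])
        with pytest.raises(AssemblyError):
            add_bridge(a, (0, EVHH), (1, EVHH))
        relaxed = new_assembly(["WT", "WT"], AssemblyRules(recruitment=False))
        assert add_bridge(relaxed, (0, EVHH), (1, EVHH)).zinc_total == 1

    def test_strict_homotypic_mode_blocks_heterotypic(self):
        a = new_assembly(["WT", "D7H"], AssemblyRules(strict_homotypic=True))
        with pytest.raises(AssemblyError):
            add_bridge(a, (0, EVHH), (1, H7H13))


class TestNamedTopologies:
    @pytest.mark.parametrize(
        "name, n_subunits, n_bridges",
        [
            ("dimer_EVHH", 2, 1),
            ("tetramer_E3H6", 4, 4),
            ("tetramer_H7H13", 4, 4),
            ("octamer", 8, 7),
            ("dodecamer", 12, 11),
            ("heterotrimer_D7H", 3, 2),
            ("heterotrimer_isoD7", 3, 2),
        ],
    )
    def test_counts_and_connectivity(self, name, n_subunits, n_bridges):
        a = build_named_assembly(name)
        assert len(a.subunits) == n_subunits
        assert a.zinc_total == n_bridges == len(a.bridges)
        assert a.is_connected()

    def test_heterotrimer_iso_wiring(self):
        a = build_named_assembly("heterotrimer_isoD7")
        central = a.subunits[1]
        assert central.variant == "isoD7"
        assert a.site_occupied(1, EVHH) and a.site_occupied(1, H6H13)
        assert a.site_occupied(0, EVHH) and a.site_occupied(2, EVHH)

    def test_unknown_topology_rejected(self):
        with pytest.raises(AssemblyError):
            build_named_assembly("hexamer")

    def test_text_round_trip(self):
        a = build_named_assembly("dodecamer")
        b = Assembly.from_text(a.to_text())
        assert len(b.subunits) == 12 and b.zinc_total == a.zinc_total
        assert b.to_text().splitlines()[1:] == a.to_text().splitlines()[1:]


def enumerate_monomer_extensions(a, pool):
    """Brute-force oracle: all (site, fresh-variant, fresh-site) triples whose
    bridge would be accepted, with the conformational gate applied."""
    out = []
    for su in a.subunits:
        for site in su.sites:
            if a.site_occupied(su.index, site):
                continue
            if site in (H7H13, H6H13) and a.site_occupied(su.index, EVHH):
                continue
            for variant in pool:
                probe = Assembly(
                    subunits=list(a.subunits) + [make_subunit(variant, 999)],
                    bridges=list(a.bridges),
                    rules=a.rules,
                )
                for t in VARIANT_SITES[variant]:
                    if probe.bridge_legal((su.index, site), (999, t)) is None:
                        out.append((su.index, site, variant, t))
    return out


class TestSeeds:
    def test_dodecamer_has_three_seeds(self):
        assert free_seed_count(build_named_assembly("dodecamer")) == 3

    def test_wild_type_monomer_has_no_seed(self):
        assert free_seed_count(new_assembly(["WT"])) == 0
        assert not can_extend(new_assembly(["WT"]), {"WT"})

    def test_dimer_seed_count_matches_enumeration(self):
        a = build_named_assembly("dimer_EVHH")
        exts = enumerate_monomer_extensions(a, {"D7H"})
        # every legal single-site extension uses the E3/H6 pair sites, so the
        # dimer offers exactly one lateral dimer-docking slot
        assert {(s, site) for s, site, _, _ in exts} == {(0, E3H6), (1, E3H6)}
        assert free_seed_count(a) == 1
        assert free_seed_count(a, unit="monomer") == len({(s, x) for s, x, _, _ in exts})

    def test_empty_assembly_cannot_extend(self):
        assert not can_extend(Assembly(), {"D7H"})

    def test_heterotrimer_extension_rules(self):
        tri = build_named_assembly("heterotrimer_D7H")
        assert not can_extend(tri, {"WT"})
        assert can_extend(tri, {"D7H"})
        assert can_extend(build_named_assembly("dodecamer"), {"D7H"})


class TestInvariants:
    def test_zinc_accounting_and_valence_under_fuzzing(self):
        rng = np.random.default_rng(11)
        for trial in range(25):
            variants = [
                ["WT", "D7H", "isoD7"][rng.integers(0, 3)] for _ in range(6)
            ]
            a = new_assembly(variants)
            for _ in range(30):
                i1, i2 = rng.integers(0, 6, size=2)
                s1 = a.subunits[i1].sites[rng.integers(0, len(a.subunits[i1].sites))]
                s2 = a.subunits[i2].sites[rng.integers(0, len(a.subunits[i2].sites))]
                reason = a.bridge_legal((i1, s1), (i2, s2))
                if reason is None:
                    a = add_bridge(a, (i1, s1), (i2, s2))
                else:
                    with pytest.raises(AssemblyError):
                        add_bridge(a, (i1, s1), (i2, s2))
                # zinc accounting
                assert a.zinc_total == len(a.bridges)
                # valence: every site holds at most one bridge
                endpoint_counts = {}
                for b in a.bridges:
                    for ep in (b.endpoint_a, b.endpoint_b):
                        endpoint_counts[ep] = endpoint_counts.get(ep, 0) + 1
                assert all(v == 1 for v in endpoint_counts.values())
                # capacity: bridges per subunit never exceed its site count
                per_subunit = {}
                for b in a.bridges:
                    for ep in (b.endpoint_a, b.endpoint_b):
                        per_subunit[ep[0]] = per_subunit.get(ep[0], 0) + 1
                for su in a.subunits:
                    assert per_subunit.get(su.index, 0) <= len(su.sites)

    def test_upgrading_wild_type_never_loses_seeds(self):
        rng = np.random.default_rng(23)
        pool = {"WT", "D7H"}
        for trial in range(15):
            variants = [["WT", "D7H"][rng.integers(0, 2)] for _ in range(5)]
            a = new_assembly(variants)
            for _ in range(12):
                i1, i2 = rng.integers(0, 5, size=2)
                s1 = a.subunits[i1].sites[rng.integers(0, len(a.subunits[i1].sites))]
                s2 = a.subunits[i2].sites[rng.integers(0, len(a.subunits[i2].sites))]
                if a.bridge_legal((i1, s1), (i2, s2)) is None:
                    a = add_bridge(a, (i1, s1), (i2, s2))
            wt_indices = [su.index for su in a.subunits if su.variant == "WT"]
            if not wt_indices:
                continue
            before_d = free_seed_count(a, pool)
            before_m = free_seed_count(a, pool, unit="monomer")
            upgraded = replace_variant(a, wt_indices[0], "D7H")
            assert free_seed_count(upgraded, pool) >= before_d
            assert free_seed_count(upgraded, pool, unit="monomer") >= before_m
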