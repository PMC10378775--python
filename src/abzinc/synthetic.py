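"""Seeded generators for every input class the pipeline consumes.

Each generator returns its dataset together with a :class:`GroundTruth` record
(planted parameters + seed) so downstream stages can be tested for exact
recovery without any instrument data.  Regeneration with the same seed is
byte-identical.

What is emulated, and what is not: the calorimetry generator adds i.i.d.
Gaussian noise to an ideal two-site isotherm (no baseline drift or first-
injection artefacts); the spectrum generator plants chelator evidence as clean
fragment ladders plus minimal zinc-carrying spans (no isotope envelopes or
intensity structure); the trajectory generator moves one side-chain centroid
per controlled residue pair with independent per-frame Bernoulli contacts (no
chain physics).  They probe the inference logic, not instrument realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .peptides import Peptide, chelation_capable_positions
from .itc import (
    BindingModel,
    TitrationCurve,
    TitrationProtocol,
    default_protocol,
    simulate_titration,
)
from .ms_mapping import PeakList, generate_fragments, precursor_mz
from .contacts import Trajectory, load_trajectory

__all__ = [
    "GroundTruth",
    "synth_itc",
    "synth_spectra",
    "synth_trajectory",
    "reference_chelator_spectra",
]


class SynthError(ValueError):
    pass


@dataclass
class GroundTruth:
    """Planted parameters of a generated dataset."""

    generator: str
    seed: int
    planted: dict
    manifest: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "generator": self.generator,
                "seed": self.seed,
                "planted": self.planted,
                "manifest": self.manifest,
            },
            sort_keys=True,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "GroundTruth":
        d = yaml.safe_load(text)
        return cls(d["generator"], d["seed"], d["planted"], d.get("manifest", {}))


# -- calorimetry -----------------------------------------------------------


def synth_itc(
    model: BindingModel,
    protocol: TitrationProtocol | None = None,
    noise_sd_fraction: float = 0.02,
    seed: int = 1,
) -> tuple[TitrationCurve, GroundTruth]:
    """An ideal isotherm plus i.i.d. Gaussian noise with standard deviation
    ``noise_sd_fraction`` times the largest absolute heat."""
    if noise_sd_fraction < 0:
        raise SynthError("noise_sd_fraction must be non-negative")
    protocol = protocol or default_protocol()
    clean = simulate_titration(model, protocol)
    heats = np.asarray(clean.heats)
    if noise_sd_fraction > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(
            0.0, noise_sd_fraction * np.max(np.abs(heats)), heats.size
        )
    curve = TitrationCurve(clean.molar_ratios, tuple(heats), protocol=protocol)
    truth = GroundTruth(
        generator="synth_itc",
        seed=seed,
        planted={
            "sites": [
                {"N": s.n, "Ka": s.ka, "dH": s.dh} for s in model.sites
            ],
            "noise_sd_fraction": noise_sd_fraction,
        },
        manifest={
            "n_injections": protocol.n_injections,
            "cell_volume_uL": protocol.cell_volume_uL,
            "cell_peptide_conc_mM": protocol.cell_peptide_conc_mM,
            "syringe_ligand_conc_mM": protocol.syringe_ligand_conc_mM,
        },
    )
    return curve, truth


# -- tandem-MS -------------------------------------------------------------


def _planted_groups(planted: Sequence[int], window: int) -> list[list[int]]:
    groups: list[list[int]] = []
    for p in sorted(planted):
        if groups and p - groups[-1][-1] <= window:
            groups[-1].append(p)
        else:
            groups.append([p])
    return groups


def _pinning_span(p: Peptide, pos: int, capable: set[int]) -> tuple[int, int, int]:
    """The shortest 1-Zn fragment span that contains ``pos``, no other capable
    position, and is mass-resolvable: annotated against the full theoretical
    fragment set (5 ppm, standard tie-breaks) it maps back to itself.

    A bare one-residue span is often degenerate (every His internal fragment
    has the same mass), so spans grow through neighbouring non-chelating
    residues until the composition is unique.
    """
    from .ms_mapping import annotate as _annotate

    first = p.numbering_offset + 1
    last = p.numbering_offset + len(p)
    theo = generate_fragments(
        p, series=("b", "y", "c", "z", "internal"), max_charge=2, max_zinc=3
    )
    theo_sorted = sorted(theo, key=lambda f: f.mz)

    def resolvable(frag) -> bool:
        tol = frag.mz * 5e-6
        cands = [f for f in theo_sorted if abs(f.mz - frag.mz) <= tol]
        best = min(
            cands,
            key=lambda f: (f.n_zinc, f.charge, f.is_internal, abs(f.mz - frag.mz)),
        )
        return best.span == frag.span and best.n_zinc == frag.n_zinc

    def realisable(i: int, j: int):
        if i == first or j == last:
            series = "b" if i == first else "y"
        else:
            series = "internal"
        for f in theo:
            if (
                f.span == (i, j)
                and f.n_zinc == 1
                and f.charge == 1
                and f.ion_series == series
            ):
                return f
        return None

    from collections import deque

    queue = deque([(pos, pos)])
    seen = {(pos, pos)}
    while queue:
        i, j = queue.popleft()
        frag = realisable(i, j)
        if frag is not None and resolvable(frag):
            return (i, j, 1)
        if j - i + 1 >= 6:
            continue
        for ni, nj in ((i, j + 1), (i - 1, j)):
            if ni < first or nj > last or (ni, nj) in seen:
                continue
            grown = ni if ni != i else nj
            if grown in capable:
                continue  # keep exactly one capable position inside
            seen.add((ni, nj))
            queue.append((ni, nj))
    raise SynthError(
        f"no mass-resolvable pinning span for position {pos}: its evidence "
        "cannot be distinguished from same-composition fragments"
    )


def synth_spectra(
    p: Peptide,
    planted_chelators: Iterable[int],
    coverage: float = 1.0,
    decoy_rate: float = 0.0,
    seed: int = 1,
    span_mode: str = "pinned",
    group_window: int = 3,
    suppression_prob: float = 0.0,
    capable_set: Iterable[str] | None = None,
) -> tuple[list[PeakList], GroundTruth]:
    """Apo and holo CID/ECD peak lists with planted chelator evidence.

    The apo spectra carry a terminal-fragment ladder sampled at the requested
    ``coverage``.  The holo spectra reuse the same ladder (so coverage gaps can
    never mimic suppression), add zinc-carrying evidence fragments, and drop
    ladder fragments whose cleavage site falls between the first and last
    member of a planted group with probability ``suppression_prob`` (a zinc
    bridge blocking backbone cleavage).

    ``span_mode="pinned"`` plants, for every chelator, the smallest fragment
    span containing it and no other capable position (one zinc each);
    ``span_mode="grouped"`` plants one 1-Zn span per group of planted positions
    within ``group_window`` of each other, plus a k-Zn span per k-member group.
    Decoy peaks (fraction ``decoy_rate`` of the real peaks) fall at random m/z
    at least 20 ppm away from every theoretical fragment.
    """
    planted = sorted(set(planted_chelators))
    if not 0 < coverage <= 1:
        raise SynthError("coverage must be in (0, 1]")
    if span_mode not in ("pinned", "grouped"):
        raise SynthError("span_mode must be 'pinned' or 'grouped'")
    capable = chelation_capable_positions(p, capable_set, include_n_terminus=False)
    bad = [pos for pos in planted if pos not in capable]
    if bad:
        raise SynthError(
            f"planted positions {bad} are not chelation-capable "
            f"(Gly/Ala and similar side chains cannot coordinate zinc)"
        )
    if not planted:
        raise SynthError("holo spectra require a non-empty planted set")

    rng = np.random.default_rng(seed)
    first = p.numbering_offset + 1
    last = p.numbering_offset + len(p)

    # shared ladder: which charge-1 terminal fragments are observed at all
    ladder: dict[str, list] = {"CID": [], "ECD": []}
    series_for = {"CID": ("b", "y"), "ECD": ("c", "z")}
    all_terminal = generate_fragments(
        p, series=("b", "y", "c", "z"), max_charge=1, max_zinc=0
    )
    for frag in all_terminal:
        act = "CID" if frag.ion_series in ("b", "y") else "ECD"
        if rng.random() < coverage:
            ladder[act].append(frag)

    # zinc evidence spans
    groups = _planted_groups(planted, group_window)
    evidence: list[tuple[int, int, int]] = []  # (start, end, n_zinc)
    if span_mode == "pinned":
        for pos in planted:
            evidence.append(_pinning_span(p, pos, capable))
    else:
        for grp in groups:
            evidence.append((grp[0], grp[-1], 1))
            if len(grp) > 1:
                evidence.append((grp[0], grp[-1], len(grp)))

    def span_fragment(i: int, j: int, nz: int):
        series = "internal"
        if i == first:
            series = "b"
            cands = generate_fragments(p, series=("b",), max_charge=1, max_zinc=nz)
        elif j == last:
            series = "y"
            cands = generate_fragments(p, series=("y",), max_charge=1, max_zinc=nz)
        else:
            cands = generate_fragments(
                p,
                series=("internal",),
                max_internal_length=j - i + 1,
                max_charge=1,
                max_zinc=nz,
            )
        for f in cands:
            if f.span == (i, j) and f.n_zinc == nz and f.ion_series == series:
                return f
        raise SynthError(f"cannot realise evidence span [{i},{j}] x{nz}Zn")

    evidence_frags = [span_fragment(i, j, nz) for i, j, nz in evidence]

    # suppression: cleavage sites interior to each planted group
    suppressed_sites: set[int] = set()
    for grp in groups:
        if len(grp) > 1 and suppression_prob > 0:
            for site in range(grp[0], grp[-1]):
                if rng.random() < suppression_prob:
                    suppressed_sites.add(site)

    def frag_site(frag) -> int:
        i, j = frag.span
        return j if frag.ion_series in ("b", "c") else i - 1

    max_zn = max(nz for _, _, nz in evidence)
    theo_mz = sorted(
        f.mz
        for f in generate_fragments(
            p, series=("b", "y", "c", "z", "internal"), max_charge=2, max_zinc=3
        )
    )

    import bisect as _b

    def decoys(n_real: int) -> list[float]:
        out = []
        n_target = int(round(decoy_rate * n_real))
        while len(out) < n_target:
            mz = float(rng.uniform(200.0, 1800.0))
            k = _b.bisect_left(theo_mz, mz)
            near = [
                theo_mz[x]
                for x in (k - 1, k)
                if 0 <= x < len(theo_mz)
            ]
            if all(abs(mz - t) / t > 20e-6 for t in near):
                out.append(mz)
        return out

    spectra: list[PeakList] = []
    for act in ("CID", "ECD"):
        apo_frags = list(ladder[act])
        apo_mz = [f.mz for f in apo_frags]
        apo_dec = decoys(len(apo_mz))
        spectra.append(
            PeakList(
                mz=tuple(apo_mz + apo_dec),
                intensity=tuple([100.0] * len(apo_mz) + [5.0] * len(apo_dec)),
                precursor_mz=precursor_mz(p, 2, 0),
                precursor_charge=2,
                precursor_n_zinc=0,
                activation=act,
                title=f"apo_{act}",
            )
        )
        holo_frags = [
            f for f in ladder[act] if frag_site(f) not in suppressed_sites
        ] + evidence_frags
        holo_mz = [f.mz for f in holo_frags]
        dec = decoys(len(holo_mz))
        spectra.append(
            PeakList(
                mz=tuple(holo_mz + dec),
                intensity=tuple([100.0] * len(holo_mz) + [5.0] * len(dec)),
                precursor_mz=precursor_mz(p, 2, max_zn),
                precursor_charge=2,
                precursor_n_zinc=max_zn,
                activation=act,
                title=f"holo_{act}",
            )
        )

    truth = GroundTruth(
        generator="synth_spectra",
        seed=seed,
        planted={
            "chelators": [int(x) for x in planted],
            "span_mode": span_mode,
            "evidence_spans": [[int(i), int(j), int(z)] for i, j, z in evidence],
            "suppressed_sites": sorted(int(s) for s in suppressed_sites),
            "coverage": coverage,
            "decoy_rate": decoy_rate,
        },
        manifest={"sequence": p.residues, "variant": p.variant},
    )
    return spectra, truth


def reference_chelator_spectra(seed: int = 1):
    """The worked-example fixture for the Taiwan-mutant domain: grouped 1-Zn
    evidence over residues 3-7 and 11-14 with full suppression of cleavages
    interior to each group, so inference should name E3, H6, H7, E11, H13, H14."""
    from .peptides import abeta16

    pep = abeta16("D7H")
    spectra, truth = synth_spectra(
        pep,
        planted_chelators={3, 6, 7, 11, 13, 14},
        coverage=1.0,
        decoy_rate=0.0,
        seed=seed,
        span_mode="grouped",
        group_window=3,
        suppression_prob=1.0,
    )
    return pep, spectra, truth


# -- trajectories ----------------------------------------------------------

_CHAIN_IDS = "ABCDEFGH"


def _pdb_atom(serial: int, name: str, resname: str, chain: str, resseq: int, xyz) -> str:
    x, y, z = xyz
    # fixed-column PDB ATOM record: name cols 13-16, resName 18-20, chainID 22,
    # resSeq 23-26, coordinates 31-54
    return (
        f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{name[0]:>2s}\n"
    )


def synth_trajectory(
    chains: Sequence[Peptide],
    contact_rates: Mapping[tuple[tuple[str, int], tuple[str, int]], float],
    n_frames: int = 2000,
    seed: int = 1,
    out_path=None,
) -> tuple[Trajectory, GroundTruth]:
    """A pseudo-atomistic multi-model PDB with planted per-pair contact rates.

    Each residue carries a backbone CA and a side-chain centroid CB.  For every
    controlled pair, an independent Bernoulli draw per frame places the second
    residue's side-chain atom at Uniform(3.2, 4.4) A (contact) or Uniform(6, 12)
    A (non-contact) from the first residue's; all uncontrolled pairs stay above
    6 A by construction (7 A residue spacing, 50 A chain separation).  A residue
    may appear in at most one controlled pair; conflicting constraints are
    geometrically unsatisfiable and rejected.
    """
    from Bio.SeqUtils import IUPACData

    if n_frames < 1:
        raise SynthError("n_frames must be >= 1")
    for rate in contact_rates.values():
        if not 0 <= rate <= 1:
            raise SynthError("contact rates must lie in [0, 1]")
    # the second residue of each pair is displaced per frame; the first stays
    # anchored.  Anchors may be shared, but a displaced residue must be unique
    # and must not anchor any pair.
    moved = [b for _a, b in contact_rates]
    anchors = {a for a, _b in contact_rates}
    if len(set(moved)) != len(moved) or anchors & set(moved):
        raise SynthError(
            "conflicting controlled pairs (a residue is displaced twice, or "
            "both anchors and is displaced): constraints are geometrically "
            "unsatisfiable"
        )

    chain_ids = _CHAIN_IDS[: len(chains)]
    one2three = {
        k.upper(): v.upper() for k, v in IUPACData.protein_letters_1to3.items()
    }

    def base_pos(chain_idx: int, pos: int) -> np.ndarray:
        return np.array([7.0 * (pos - 1), 50.0 * chain_idx, 0.0])

    rng = np.random.default_rng(seed)
    pair_list = list(contact_rates.items())
    draws = {
        pair: rng.random(n_frames) < rate for pair, rate in pair_list
    }
    dists = {
        pair: np.where(
            draws[pair],
            rng.uniform(3.2, 4.4, n_frames),
            rng.uniform(6.0, 12.0, n_frames),
        )
        for pair, _ in pair_list
    }

    chain_index = {cid: k for k, cid in enumerate(chain_ids)}
    lines: list[str] = []
    for frame in range(n_frames):
        lines.append(f"MODEL     {frame + 1:4d}\n")
        serial = 1
        for ci, pep in enumerate(chains):
            cid = chain_ids[ci]
            for pos in pep.positions:
                res3 = one2three[pep.residue_at(pos)]
                ca = base_pos(ci, pos)
                cb = ca + np.array([0.0, 1.5, 0.0])
                key = (cid, pos)
                for (a, b), dvals in dists.items():
                    if key == b:
                        a_ci = chain_index[a[0]]
                        a_cb = base_pos(a_ci, a[1]) + np.array([0.0, 1.5, 0.0])
                        cb = a_cb + np.array([0.0, 0.0, dvals[frame]])
                        ca = cb + np.array([0.0, 1.5, 0.0])
                lines.append(_pdb_atom(serial, "CA", res3, cid, pos, ca))
                serial += 1
                lines.append(_pdb_atom(serial, "CB", res3, cid, pos, cb))
                serial += 1
        lines.append("ENDMDL\n")
    lines.append("END\n")
    text = "".join(lines)

    if out_path is None:
        import tempfile, os

        fd, out_path = tempfile.mkstemp(suffix=".pdb", prefix="abzinc_traj_")
        os.close(fd)
    with open(out_path, "w") as fh:
        fh.write(text)

    truth = GroundTruth(
        generator="synth_trajectory",
        seed=seed,
        planted={
            "contact_rates": {
                f"{a[0]}:{a[1]}-{b[0]}:{b[1]}": float(rate)
                for (a, b), rate in pair_list
            },
            "n_frames": n_frames,
        },
        manifest={
            "path": str(out_path),
            "chains": {
                chain_ids[i]: chains[i].residues for i in range(len(chains))
            },
        },
    )
    return load_trajectory(out_path), truth
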