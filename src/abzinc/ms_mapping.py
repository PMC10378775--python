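"""Tandem-MS localization of zinc-chelating residues.

Electrospray of the metal-binding domain with zinc acetate yields monomer and
dimer complexes carrying several zinc adducts.  CID (b/y) and ECD (c/z) spectra
of the zinc-bound monomers are annotated against a theoretical fragment set in
which each retained zinc replaces two protons, and the chelating residues are
deduced by intersecting the spans of fragments that carry different numbers of
zinc ions: the smallest zinc-carrying spans localize the chelators, and backbone
cleavages that disappear in the holo spectra mark possible zinc bridges.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peptides import (
    PROTON_MONO,
    RESIDUE_MASS,
    WATER_MONO,
    AMIDE_DELTA,
    ZN_ADDUCT_DELTA,
    Peptide,
    chelation_capable_positions,
)

__all__ = [
    "FragmentIon",
    "PeakList",
    "AnnotatedSpectrum",
    "ChelatorReport",
    "generate_fragments",
    "annotate",
    "infer_chelators",
    "read_mgf",
    "write_mgf",
    "read_peak_table",
    "annotation_table",
]

#: c ions gain NH3 over b ions; z-dot ions are y - NH2.
_NH3 = 17.02654910112
_NH2 = 16.01872406905

TERMINAL_SERIES = ("b", "y", "c", "z")


class MsError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical (or assigned) fragment with a zinc adduct count.

    ``span`` is the inclusive residue interval in peptide numbering; terminal
    series anchor at a terminus, ``internal`` fragments are b-type double
    backbone cleavages.
    """

    ion_series: str
    span: tuple[int, int]
    charge: int
    n_zinc: int
    neutral_mass: float

    @property
    def mz(self) -> float:
        return (self.neutral_mass + self.charge * PROTON_MONO) / self.charge

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1

    @property
    def is_internal(self) -> bool:
        return self.ion_series == "internal"

    def label(self) -> str:
        i, j = self.span
        zn = f"+{self.n_zinc}Zn" if self.n_zinc else ""
        if self.is_internal:
            return f"internal[{i}-{j}]{zn}^{self.charge}+"
        idx = self.length
        return f"{self.ion_series}{idx}{zn}^{self.charge}+"


@dataclass(frozen=True)
class PeakList:
    """An experimental (or synthetic) peak list: (m/z, intensity) pairs plus
    optional precursor metadata and the activation type."""

    mz: tuple[float, ...]
    intensity: tuple[float, ...]
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    precursor_n_zinc: int | None = None
    activation: str = "CID"
    title: str = ""

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise MsError("mz and intensity lengths differ")
        if any(m <= 0 for m in self.mz):
            raise MsError("m/z values must be positive")
        if any(i < 0 for i in self.intensity):
            raise MsError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class AnnotatedSpectrum:
    """Peak assignments at a ppm tolerance; unmatched peaks stay in ``unassigned``."""

    peaks: PeakList
    assignments: dict[int, FragmentIon]  # peak index -> retained fragment
    unassigned: tuple[int, ...]
    tolerance_ppm: float

    @property
    def zinc_assignments(self) -> list[FragmentIon]:
        return [f for f in self.assignments.values() if f.n_zinc > 0]

    @property
    def is_holo(self) -> bool:
        if self.peaks.precursor_n_zinc is not None:
            return self.peaks.precursor_n_zinc > 0
        return bool(self.zinc_assignments)

    def cleavage_sites(self, zinc_only: bool | None = None) -> set[int]:
        """Inter-residue cleavage positions evidenced by the assignments.

        Site k lies between residues k and k+1.  ``zinc_only`` filters for
        zinc-carrying (True) or zinc-free (False) assignments.
        """
        sites: set[int] = set()
        for frag in self.assignments.values():
            if zinc_only is True and frag.n_zinc == 0:
                continue
            if zinc_only is False and frag.n_zinc > 0:
                continue
            i, j = frag.span
            if frag.ion_series in ("b", "c"):
                sites.add(j)
            elif frag.ion_series in ("y", "z"):
                sites.add(i - 1)
            else:
                sites.update((i - 1, j))
        return sites


@dataclass
class ChelatorReport:
    """Ranked zinc-chelator candidates from fragment-intersection evidence."""

    candidate_scores: dict[int, float]
    minimal_zinc_spans: list[tuple[int, int, int]]  # (start, end, n_zinc)
    cleavage_suppressed_regions: list[tuple[int, int]]
    final_candidates: list[int]
    flagged_empty: bool = False

    def summary(self) -> str:
        lines = ["Zinc-chelator inference"]
        if self.flagged_empty:
            lines.append("  no zinc-carrying assignments: report empty")
        lines.append(
            "  minimal zinc spans: "
            + ", ".join(f"[{a}-{b}]x{z}Zn" for a, b, z in self.minimal_zinc_spans)
        )
        if self.cleavage_suppressed_regions:
            lines.append(
                "  cleavage-suppressed regions: "
                + ", ".join(f"[{a}-{b}]" for a, b in self.cleavage_suppressed_regions)
            )
        lines.append("  candidates (position: score):")
        for pos in sorted(self.candidate_scores, key=lambda p: -self.candidate_scores[p]):
            mark = "*" if pos in self.final_candidates else " "
            lines.append(f"   {mark} {pos:3d}: {self.candidate_scores[pos]:.3f}")
        return "\n".join(lines)


# -- theoretical fragments -------------------------------------------------


def _span_residue_sum(p: Peptide, i: int, j: int) -> float:
    off = p.numbering_offset
    return sum(RESIDUE_MASS[aa] for aa in p.residues[i - off - 1 : j - off])


def generate_fragments(
    p: Peptide,
    series: Iterable[str] = ("b", "y"),
    max_internal_length: int = 8,
    max_charge: int = 2,
    max_zinc: int = 0,
    capable_set: Iterable[str] | None = None,
    enforce_capability: bool = True,
) -> list[FragmentIon]:
    """All terminal fragments of the requested series plus b-type internal
    fragments, at charges 1..max_charge and zinc counts 0..max_zinc.

    Each retained zinc shifts the neutral mass by Zn - 2H (charge is carried by
    protons).  With ``enforce_capability`` a fragment may carry at most as many
    zinc ions as it has chelation-capable positions (the N-terminal amine counts
    for fragments containing residue 1 of a free-amine peptide).
    """
    series = set(series)
    if not series:
        raise MsError("series must be non-empty")
    unknown = series - set(TERMINAL_SERIES) - {"internal"}
    if unknown:
        raise MsError(f"unknown ion series {sorted(unknown)}")
    if max_charge < 1:
        raise MsError("max_charge must be >= 1")

    capable = chelation_capable_positions(p, capable_set)
    first = p.numbering_offset + 1
    last = p.numbering_offset + len(p)

    def capacity(i: int, j: int) -> int:
        k = sum(1 for pos in capable if i <= pos <= j)
        if i == first and p.numbering_offset in capable:
            k += 1  # free alpha-amine rides on the N-terminal fragment
        return k

    c_term_delta = AMIDE_DELTA if p.c_terminal_amide else 0.0
    frags: list[FragmentIon] = []

    def emit(ion_series: str, i: int, j: int, base_mass: float) -> None:
        cap = capacity(i, j) if enforce_capability else max_zinc
        for nz in range(0, min(max_zinc, cap) + 1):
            mass = base_mass + nz * ZN_ADDUCT_DELTA
            for z in range(1, max_charge + 1):
                frags.append(FragmentIon(ion_series, (i, j), z, nz, mass))

    for n in range(1, len(p)):
        i_n, j_n = first, first + n - 1  # N-terminal fragment of length n
        i_c, j_c = last - n + 1, last  # C-terminal fragment of length n
        nsum = _span_residue_sum(p, i_n, j_n)
        csum = _span_residue_sum(p, i_c, j_c)
        if "b" in series:
            emit("b", i_n, j_n, nsum)
        if "c" in series:
            emit("c", i_n, j_n, nsum + _NH3)
        if "y" in series:
            emit("y", i_c, j_c, csum + WATER_MONO + c_term_delta)
        if "z" in series:
            # z-dot radical ions
            emit("z", i_c, j_c, csum + WATER_MONO + c_term_delta - _NH2)
    if "internal" in series:
        for i in range(first + 1, last):
            for j in range(i, min(i + max_internal_length - 1, last - 1) + 1):
                emit("internal", i, j, _span_residue_sum(p, i, j))
    return frags


def precursor_neutral_mass(p: Peptide, n_zinc: int = 0) -> float:
    return p.monoisotopic_mass + n_zinc * ZN_ADDUCT_DELTA


def precursor_mz(p: Peptide, charge: int, n_zinc: int = 0) -> float:
    return (precursor_neutral_mass(p, n_zinc) + charge * PROTON_MONO) / charge


# -- annotation ------------------------------------------------------------


def annotate(
    peaks: PeakList,
    p: Peptide,
    tolerance_ppm: float = 5.0,
    series: Iterable[str] = ("b", "y", "c", "z", "internal"),
    max_internal_length: int = 8,
    max_charge: int = 2,
    max_zinc: int = 3,
    capable_set: Iterable[str] | None = None,
) -> AnnotatedSpectrum:
    """Match peaks to theoretical fragments within a ppm tolerance.

    Ties are broken in favour of fewer zinc adducts, then lower charge, then
    terminal over internal series, then smaller mass error.  When the precursor
    zinc count is known, assignments cannot carry more zinc than the precursor.
    """
    if len(peaks) == 0:
        raise MsError("empty peak list")
    if peaks.precursor_n_zinc is not None:
        max_zinc = min(max_zinc, peaks.precursor_n_zinc)
    frags = generate_fragments(
        p,
        series=series,
        max_internal_length=max_internal_length,
        max_charge=max_charge,
        max_zinc=max_zinc,
        capable_set=capable_set,
    )
    frags.sort(key=lambda f: f.mz)
    mzs = [f.mz for f in frags]

    assignments: dict[int, FragmentIon] = {}
    unassigned: list[int] = []
    for idx, mz in enumerate(peaks.mz):
        tol = mz * tolerance_ppm * 1e-6
        lo = bisect.bisect_left(mzs, mz - tol)
        hi = bisect.bisect_right(mzs, mz + tol)
        candidates = frags[lo:hi]
        if not candidates:
            unassigned.append(idx)
            continue
        best = min(
            candidates,
            key=lambda f: (f.n_zinc, f.charge, f.is_internal, abs(f.mz - mz) / mz),
        )
        assignments[idx] = best
    return AnnotatedSpectrum(peaks, assignments, tuple(unassigned), tolerance_ppm)


def annotation_table(spectrum: AnnotatedSpectrum) -> pd.DataFrame:
    """Assignments as a delimited-ready table (one row per assigned peak)."""
    rows = []
    for idx, frag in sorted(spectrum.assignments.items()):
        mz = spectrum.peaks.mz[idx]
        rows.append(
            {
                "peak_mz": mz,
                "series": frag.ion_series,
                "span_start": frag.span[0],
                "span_end": frag.span[1],
                "charge": frag.charge,
                "n_zinc": frag.n_zinc,
                "ppm_error": (mz - frag.mz) / frag.mz * 1e6,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_mz", "series", "span_start", "span_end", "charge", "n_zinc", "ppm_error",
        ],
    )


# -- chelator inference ----------------------------------------------------


def _minimal_spans(spans: dict[tuple[int, int, int], int]) -> dict[tuple[int, int, int], int]:
    """Keep spans with no assigned strict sub-span at the same zinc count."""
    keep = {}
    for (i, j, z), w in spans.items():
        minimal = True
        for (a, b, z2) in spans:
            if z2 == z and (a, b) != (i, j) and i <= a and b <= j:
                minimal = False
                break
        if minimal:
            keep[(i, j, z)] = w
    return keep


def infer_chelators(
    spectra: Sequence[AnnotatedSpectrum],
    p: Peptide,
    options: Mapping | None = None,
) -> ChelatorReport:
    """Deduce zinc-chelating residues by fragment intersection.

    Steps (each switchable through ``options``):

    1. pool zinc-carrying assigned spans across spectra, per zinc count
       (an assignment carrying k zinc inside a span with fewer than k capable
       positions is discarded as chemically impossible);
    2. keep the minimal spans (no assigned sub-span at the same zinc count);
    3. apportion each minimal span's k zinc among the chelation-capable
       positions it covers, weighting by how many spectra produced the span,
       and normalise scores to a maximum of 1;
    4. flag cleavage-suppressed regions: inter-residue sites cleaved in apo
       assignments but never in holo ones (possible zinc bridge);
    5. final candidates: capable positions scoring at least ``threshold``
       (default 0.5) plus capable positions interior to suppressed regions.

    Options: ``threshold``, ``capable_set``, ``scoring`` ("apportion" |
    "containment"), ``detect_suppression`` (bool), ``include_n_terminus``.
    """
    opts = dict(options or {})
    threshold = float(opts.pop("threshold", 0.5))
    capable_set = opts.pop("capable_set", None)
    scoring = opts.pop("scoring", "apportion")
    detect_suppression = bool(opts.pop("detect_suppression", True))
    include_nterm = bool(opts.pop("include_n_terminus", True))
    if opts:
        raise MsError(f"unknown options: {sorted(opts)}")
    if scoring not in ("apportion", "containment"):
        raise MsError("scoring must be 'apportion' or 'containment'")

    capable = sorted(
        chelation_capable_positions(p, capable_set, include_n_terminus=include_nterm)
    )
    first = p.numbering_offset + 1

    def capable_in(i: int, j: int) -> list[int]:
        out = [pos for pos in capable if i <= pos <= j]
        if i == first and p.numbering_offset in capable:
            out.append(p.numbering_offset)
        return out

    # 1. pool zinc-carrying spans (weight = number of spectra showing the span)
    span_weight: dict[tuple[int, int, int], int] = {}
    for spec in spectra:
        seen = set()
        for frag in spec.zinc_assignments:
            i, j = frag.span
            if len(capable_in(i, j)) < frag.n_zinc:
                continue  # impossible: more zinc than chelating positions
            key = (i, j, frag.n_zinc)
            if key not in seen:
                seen.add(key)
                span_weight[key] = span_weight.get(key, 0) + 1

    if not span_weight:
        return ChelatorReport({pos: 0.0 for pos in capable}, [], [], [], flagged_empty=True)

    # 2. minimal spans per zinc count
    minimal = _minimal_spans(span_weight)

    # 3. scores
    raw = {pos: 0.0 for pos in capable}
    for (i, j, z), w in minimal.items():
        inside = capable_in(i, j)
        if not inside:
            continue
        if scoring == "apportion":
            share = w * z / len(inside)
            for pos in inside:
                raw[pos] += share
        else:
            for pos in inside:
                raw[pos] += w
    peak_score = max(raw.values()) if raw else 0.0
    scores = {
        pos: (v / peak_score if peak_score > 0 else 0.0) for pos, v in raw.items()
    }

    # 4. cleavage suppression: sites cut in apo spectra but never in holo
    suppressed_regions: list[tuple[int, int]] = []
    if detect_suppression:
        apo_sites: set[int] = set()
        holo_sites: set[int] = set()
        any_holo = False
        for spec in spectra:
            if spec.is_holo:
                any_holo = True
                holo_sites |= spec.cleavage_sites()
            else:
                apo_sites |= spec.cleavage_sites()
        if any_holo:
            suppressed = sorted(apo_sites - holo_sites)
            run: list[int] = []
            for s in suppressed:
                if run and s != run[-1] + 1:
                    if len(run) > 1:
                        suppressed_regions.append((run[0], run[-1] + 1))
                    run = []
                run.append(s)
            if len(run) > 1:
                suppressed_regions.append((run[0], run[-1] + 1))

    # 5. final candidates
    final = {pos for pos, s in scores.items() if s >= threshold}
    for a, b in suppressed_regions:
        final |= {pos for pos in capable if a < pos < b}
    ranked = sorted(final, key=lambda pos: (-scores.get(pos, 0.0), pos))

    return ChelatorReport(
        candidate_scores=scores,
        minimal_zinc_spans=sorted(minimal),
        cleavage_suppressed_regions=suppressed_regions,
        final_candidates=ranked,
    )


# -- I/O -------------------------------------------------------------------


def read_mgf(path) -> list[PeakList]:
    """Read peak lists from MGF.  Zinc counts and activation are taken from
    optional ``ZINC=`` / ``ACTIVATION=`` params when present."""
    from pyteomics import mgf

    out = []
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec.get("params", {})
            pep = params.get("pepmass", (None,))
            charge = params.get("charge")
            out.append(
                PeakList(
                    mz=tuple(float(v) for v in spec["m/z array"]),
                    intensity=tuple(float(v) for v in spec["intensity array"]),
                    precursor_mz=float(pep[0]) if pep and pep[0] else None,
                    precursor_charge=int(charge[0]) if charge else None,
                    precursor_n_zinc=(
                        int(params["zinc"]) if "zinc" in params else None
                    ),
                    activation=str(params.get("activation", "CID")).upper(),
                    title=str(params.get("title", "")),
                )
            )
    return out


def write_mgf(spectra: Iterable[PeakList], path) -> None:
    with open(path, "w") as fh:
        for k, s in enumerate(spectra):
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.title or f'spectrum_{k + 1}'}\n")
            if s.precursor_mz is not None:
                fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.precursor_charge is not None:
                fh.write(f"CHARGE={s.precursor_charge}+\n")
            if s.precursor_n_zinc is not None:
                fh.write(f"ZINC={s.precursor_n_zinc}\n")
            fh.write(f"ACTIVATION={s.activation}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f} {inten:.2f}\n")
            fh.write("END IONS\n")


def read_peak_table(path, **kwargs) -> PeakList:
    """Two-column delimited (mz, intensity) reader."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = list(df.columns[:2])
    return PeakList(
        mz=tuple(float(v) for v in df[cols[0]]),
        intensity=tuple(float(v) for v in df[cols[1]]),
        **kwargs,
    )
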