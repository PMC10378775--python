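import numpy as np
import pytest

from abzinc.itc import TitrationProtocol, default_protocol
from abzinc.peptides import abeta16


@pytest.fixture(scope="session")
def d7h():
    return abeta16("D7H")


@pytest.fixture(scope="session")
def wt():
    return abeta16("WT")


@pytest.fixture(scope="session")
def protocol() -> TitrationProtocol:
    return default_protocol()


# -- independent ITC oracle ------------------------------------------------


def oracle_titration_heats(model, protocol, grid_points: int = 4000) -> np.ndarray:
    """Brute-force reference for the per-injection heats (kcal per mol of
    injectant): the free-ligand mass balance is solved per injection by a dense
    scan for the sign change followed by plain scalar bisection.  Shares only
    the stated dilution formulas with the implementation, not its code path."""
    v0 = protocol.cell_volume_uL
    m0 = protocol.cell_peptide_conc_mM * 1e-3
    x0 = protocol.syringe_ligand_conc_mM * 1e-3
    v0_L = v0 * 1e-6

    def balance(L, m_tot, x_tot):
        bound = 0.0
        for s in model.sites:
            bound += s.n * s.ka * L / (1.0 + s.ka * L)
        return L + m_tot * bound - x_tot

    heats = []
    q_prev = 0.0
    cum = 0.0
    for dv in protocol.injection_volumes_uL:
        cum += dv
        c = cum / v0
        m_tot = m0 * (1 - c / 2) / (1 + c / 2)
        x_tot = x0 * c * (1 - c / 2)
        # dense scan for the bracketing interval
        grid = np.linspace(0.0, x_tot, grid_points)
        vals = [balance(L, m_tot, x_tot) for L in grid]
        lo, hi = 0.0, x_tot
        for k in range(1, grid_points):
            if vals[k - 1] <= 0.0 <= vals[k]:
                lo, hi = grid[k - 1], grid[k]
                break
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if balance(mid, m_tot, x_tot) > 0:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-16 * max(x_tot, 1e-30):
                break
        L = 0.5 * (lo + hi)
        q = 0.0
        for s in model.sites:
            q += s.n * s.dh * s.ka * L / (1.0 + s.ka * L)
        q *= v0_L * m_tot
        dq = q - q_prev + (dv / v0) * (q + q_prev) / 2
        heats.append(dq / (dv * 1e-6 * x0))
        q_prev = q
    return np.array(heats)


# -- independent fragment-mass oracle --------------------------------------

#: monoisotopic residue masses from a published amino-acid mass table,
#: written down independently of the implementation's source
ORACLE_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_WATER = 18.010565
ORACLE_PROTON = 1.0072765
ORACLE_NH3 = 17.026549
ORACLE_NH2 = 16.018724
ORACLE_ZN = 63.929142
ORACLE_H = 1.007825


def oracle_fragment_neutral_mass(sequence, frag, c_terminal_amide=True, offset=0):
    """Residue-sum reference mass for a fragment of ``sequence`` (1-based spans)."""
    i, j = frag.span
    total = sum(ORACLE_RESIDUE_MASS[aa] for aa in sequence[i - 1 - offset: j - offset])
    n = len(sequence)
    if frag.ion_series == "b":
        pass
    elif frag.ion_series == "c":
        total += ORACLE_NH3
    elif frag.ion_series in ("y", "z"):
        total += ORACLE_WATER
        if c_terminal_amide:
            total += ORACLE_NH2 - (ORACLE_WATER - ORACLE_H)  # OH -> NH2
        if frag.ion_series == "z":
            total -= ORACLE_NH2
    elif frag.ion_series == "internal":
        pass
    total += frag.n_zinc * (ORACLE_ZN - 2 * ORACLE_H)
    return total
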