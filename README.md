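# abzinc

Zinc-driven oligomerization analysis of the amyloid-beta metal-binding domain
(Abeta residues 1–16), centred on the early-onset Taiwan mutant D7H.

Zinc ions control the aggregation of amyloid-beta: the 1–16 fragment is the
peptide's metal-binding domain, and modified isoforms (the D7H mutant, the
isoaspartate-7 isoform) oligomerize through *intermolecular* zinc bridges in
which a residue pair from each of two peptides jointly coordinates one Zn²⁺
(for example E11/H14:ZN:E11/H14, built on the rigid 11-EVHH-14 segment).
`abzinc` implements, as one tested pipeline, the computational chain used to
establish that mechanism:

* **`abzinc.itc`** — isothermal titration calorimetry. A forward model of the
  perfusion-cell titration for one or two independent classes of sites
  (per-site stoichiometry *N*, association constant *K_a*, enthalpy *ΔH*;
  cumulative heat `Q = V₀·M·Σᵢ Nᵢ ΔHᵢ KᵢL/(1+KᵢL)` with the free ligand `L`
  solved from the mass balance), exposed statsmodels-style: build a
  `ZincTitrationModel` from a `TitrationCurve`, call `.fit()`, read estimates,
  bootstrap uncertainties, AICc, `summary()` and `plot()` off the results
  object. Model selection between one and two site classes uses corrected AIC.
  A fractional high-affinity stoichiometry (*N* < 1) signals a *shared*,
  intermolecular site — the calorimetric fingerprint of oligomerization.
* **`abzinc.ms_mapping`** — tandem-MS localization of the zinc chelators.
  Theoretical b/y/c/z and internal fragments with zinc adducts (each retained
  Zn replaces two protons), ppm-tolerance spectrum annotation, and a
  fragment-intersection algorithm: minimal zinc-carrying spans apportion their
  zinc among chelation-capable residues (Asp/Glu/His/Cys/Met/Tyr — never
  Gly/Ala), and cleavage suppression in holo spectra marks bridged regions.
* **`abzinc.contacts`** — residue-contact census over multi-chain MD
  trajectories (minimum side-chain heavy-atom distance, default cutoff 4.5 Å)
  plus steric-exclusion logic that turns the census into the set of feasible
  zinc-mediated interfaces.
* **`abzinc.assembly`** — combinatorics of zinc-bridged oligomer growth:
  variant-specific interface sites (WT: E11/H14 + E3/H6; D7H adds H7/H13;
  isoD7: E11/H14 + H6/H13), bridge valence and compatibility rules, the named
  dimer/tetramer/octamer/dodecamer topologies and the WT·(D7H)·WT and
  WT·(isoD7)·WT heterotrimers, with polymerization-seed counting.
* **`abzinc.synthetic`** — seeded generators (isotherms, fragment spectra,
  pseudo-atomistic trajectories) with ground-truth manifests, standing in for
  the calorimeter, the mass spectrometer, and the MD engine.
* **`abzinc.pipeline` / CLI `abzinc`** — the stages wired end to end.

## Worked example

```python
import numpy as np
from abzinc import PUBLISHED_PARAMS, ZincTitrationModel, default_protocol, synth_itc

curve, truth = synth_itc(PUBLISHED_PARAMS["D7H-AB16"], default_protocol(),
                         noise_sd_fraction=0.02, seed=1)
res = ZincTitrationModel(curve, n_sites=2).fit(n_bootstrap=0)
print(res.summary())
```

prints

```
Zinc titration fit: independent-sites isotherm
  injections: 20   site classes: 2
  RSS 0.1236   RMSE 0.0786   AICc -83.27

site      N  Ka_M^-1  dH_kcal_mol  N_se  Ka_se  dH_se
high 0.4457    1e+08       -8.163   NaN    NaN    NaN
 low 0.9114 1.96e+04       -10.38   NaN    NaN    NaN
```

The low-affinity class recovers the planted (N = 1, K_a = 2.3 × 10⁴ M⁻¹,
ΔH = −10.3 kcal/mol) site well; the high-affinity site (planted N = 0.35,
K_a = 48 × 10⁴ M⁻¹) is weakly identified at this noise level — its N drifts
high and its K_a toward the fitting bound, a real identifiability limit of
two-site isotherms whose site classes have similar enthalpies (see
`docs/methods.md`).

The whole chain on synthetic data:

```bash
abzinc run --seed 1            # ITC fit -> chelators -> interfaces -> assemblies
abzinc assemble --topology dodecamer
```

The assembly report for the dodecamer prints `12 subunits, 11 zinc bridges,
connected=True` and `free polymerization seeds: 3`: three lateral slots where
a fresh E11/H14 dimer can dock. The chelator stage names E3, H6, H7, E11,
H13, H14; the contact stage selects exactly the three interfaces
E11/H14:ZN:E11/H14, E3/H6:ZN:E3/H6 and H7/H13:ZN:H7/H13.

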