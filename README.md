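# phytosol

Thermodynamic screening of agrochemical–plant-surface interactions with
solubility parameters.

Aerial plant organs are covered by a lipid-rich cuticle whose outermost
epicuticular waxes (n-alkanes, β-diketones, triterpenoids) control how
surface-applied sprays — fertilisers, fungicides, insecticides, surfactants —
wet and dissolve into the surface. Whether a chemical partitions into a
surface is, to first order, a question of *cohesive energy matching*:
materials with similar total solubility parameters δ tend to be mutually
soluble. `phytosol` implements this screening for plant surfaces from both
directions:

1. **Group contributions (van Krevelen–Hoftyzer).** For a molecule with
   molar volume *v* and structural-group inventory {gᵢ: nᵢ},

   δ_d = Σ nᵢF_dᵢ / v,  δ_p = f_sym · √(Σ (nᵢF_pᵢ)²) / v,  δ_h = √(Σ nᵢE_hᵢ / v),
   δ = √(δ_d² + δ_p² + δ_h²)   (MJ^1/2 m^-3/2 ≡ MPa^1/2),

   with molar attraction constants F_d, F_p and hydrogen-bond energies E_h
   from the canonical 20-group table and a symmetry factor f_sym (0.50 for
   one plane of symmetry, 0.25 for two, 0 beyond).

2. **Contact angles (van Oss–Chaudhury–Good).** From advancing angles of
   water, glycerol and diiodomethane on an intact surface, the toolkit
   solves W_a = γ_L(1+cos θ) = 2[√(γ^LW γ_L^LW) + √(γ⁺γ_L⁻) + √(γ⁻γ_L⁺)]
   for the Lifshitz–van der Waals and acid–base components, then converts
   the total surface free energy to a surface solubility parameter
   δ_θ = √e_c with e_c = (γ_s/0.75)^(3/2).

3. **Affinity screening.** Δδ = |δ_chemical − δ_surface| against either the
   dominant-wax basis (δ_wax) or the contact-angle basis (δ_θ), classified
   by the Greenhalgh bands (Δδ < 7 miscible, Δδ > 10 immiscible).

All compounds from the source study ship as validated fixtures: 13
epicuticular waxes, 4 cutin monomers (with their esterification variants),
2 cell-wall polysaccharide monomers and 11 agrochemicals, plus the three
model surfaces (juvenile *Eucalyptus globulus* leaf, pepper fruit, peach
fruit) with their measured contact angles. The layered solubility-gradient
report shows δ rising from the wax surface (≈16) through esterified cutin
(17–21) to the polysaccharide-rich cell wall (>31).

## Worked example

```python
from phytosol import (MoleculeSpec, compute_hansen, analyze_surface,
                      get_surface, delta_difference, classify_miscibility)

# group-contribution parameters of urea (2 -NH2 + 1 -CO-, one symmetry plane)
spec = MoleculeSpec(
    name="urea", formula="CH4N2O",
    groups={"-NH2": 2, "-CO-": 1},
    molar_volume=45.2, symmetry_planes=1, role="agrochemical",
)
print(compute_hansen(spec).parameters.rounded())
# (18.8, 8.5, 20.4, 29.0)

# surface energetics of the pepper fruit from its measured contact angles
prof = analyze_surface(get_surface("pepper").angle_set)
print(f"gamma_LW={prof.gamma_lw:.1f} gamma+={prof.gamma_plus:.1f} "
      f"gamma-={prof.gamma_minus:.1f} gamma={prof.gamma_total:.1f} "
      f"polarity={prof.polarity:.1f}% delta_theta={prof.delta_theta:.1f}")
# gamma_LW=28.1 gamma+=1.4 gamma-=3.9 gamma=32.7 polarity=14.1% delta_theta=17.0

# affinity of the Genapol X-80 surfactant (delta_m = 19.5) for that surface
d = delta_difference(19.5, prof.delta_theta)
print(round(d, 1), classify_miscibility(d))
# 2.5 miscible
```

The urea line reads: dispersion 18.8, polar 8.5 (halved by the molecular
symmetry), hydrogen-bonding 20.4, total 29.0 MJ^1/2 m^-3/2 — a strongly
hydrogen-bonding solute, hence a poor match (Δδ ≈ 13) for an n-alkane wax at
δ ≈ 16. The pepper surface combines a dispersive component of 28.1 mJ m⁻²
with a mostly electron-donor acid–base part, giving δ_θ = 17.0; Genapol X-80
at Δδ = 2.5 is the best-matched agrochemical in the built-in screen.

The same operations are exposed on the command line:

```sh
phytosol registry export --what compounds --out compounds.json
phytosol hansen --in compounds.json --out parameters.csv
phytosol registry export --what angles --out angles.csv
phytosol surface --angles angles.csv --out surfaces.csv
phytosol affinity --out affinity.csv --plot affinity.png
phytosol gradient
```

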