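# lineactant

Lattice Monte Carlo simulations and quantification tools for **DNA-origami
line-actants (DOLAs)** — flat DNA nanostructures that adsorb to the
one-dimensional boundary between coexisting lipid phases and stabilize it,
the way surfactants stabilize two-dimensional interfaces.

The package is aimed at membrane biophysicists and DNA nanotechnologists
who want to (i) simulate how interface-active inclusions alter domain
coarsening in phase-separated membranes, (ii) predict how strongly a given
tile design enriches the line-interface, and (iii) extract line-partitioning
coefficients from fluorescence line scans.

## What it implements

**Lattice membrane model.** A two-dimensional Ising model on a periodic
triangular lattice: spin *s* = +1 is liquid-disordered (L_d), *s* = −1 is
liquid-ordered (L_o), with Hamiltonian

```
H = −J Σ_<ij> s_i s_j  −  Σ_anchors J_a s̃_a ,     s̃_a = Σ_{star(a)} s_i
```

where the star sum runs over the anchor's host site and its six neighbours.
Dynamics are Kawasaki spin exchanges (composition-conserving) with
Metropolis acceptance; rigid rectangular tiles carrying two opposing rows
of anchors (sT anchors prefer L_d, dC anchors prefer L_o) make translation
and ±60° rotation moves with hard-core exclusion. Defaults: J = 0.55 k_BT
(subcritical: the triangular-lattice critical coupling is ln 3 / 4 ≈ 0.275),
J_sT = 0.136 k_BT, J_dC = −0.057 k_BT, composition ratio n(−1)/n(+1) = 2/3,
tile coverage σ = 30%.

**Calibration.** An anchor's bulk L_d→L_o transfer flips its star from +7
to −7, so couplings follow from measured partitioning free energies as
J_a = ΔG_p,Lo / 14 (0.136 and −0.057 k_BT for ΔG = 1.9 and −0.8 k_BT).

**Line-adsorption model.** Bulk tiles as a 2D lattice gas in equilibrium
with a 1D Tonks gas of hard rods (length ℓ = 90 nm) in the ξ = 8 nm
interface band, binding free energy ΔG_line = n_dC · ΔG_dC. Predicts the
occupied line fraction φ(σ) and the line-partitioning coefficient
K_p,int(σ) (band density / whole-vesicle average density), and inverts
measured K_p,int to a coverage estimate with ξ-sensitivity bands.

**Profile quantification.** Fits diffraction-blurred line scans with
I(x) = B_Ld + (B_Lo−B_Ld) Φ((x−x₀)/w) + A e^{−(x−x₀)²/2w²} and converts
the fit to K_p,int = (A w √(2π)/ξ + step(x₀)) / (area-weighted baseline).

**Synthetic data.** Deterministic generators for noisy profiles with known
K_p,int, equatorial ring images of Janus vesicles, and named lattice
configurations — every pipeline input can be produced with ground truth.

## Worked example

```python
import lineactant as la

# couplings from measured partitioning free energies
print(round(la.j_from_partitioning(1.9), 3))    # 0.136
print(round(la.j_from_partitioning(-0.8), 3))   # -0.057

# line occupancy predicted for the 12-anchor-pair design at 30% coverage
print(round(la.predict_phi(0.30, "12x"), 3))    # 0.836

# a small quench: tiles pin the interface
spec = la.LatticeSpec(48, 48)
layout = la.AnchorLayout.design("12x", nm_per_site=4.0)
rs = la.run_replicates(
    spec, layout, la.ModelParams(sigma=0.30),
    la.Schedule(t_mc=50_000, stride=25_000, n_replicates=3), base_seed=7,
)
print(rs.aggregate[["L_mean", "phi_mean"]].round(2))
```

which prints

```
0.136
-0.057
0.836
        L_mean  phi_mean
cycle
0      3310.67      0.34
25000   498.67      0.51
50000   466.00      0.46
```

— the interface length `L` (unlike-spin bonds) collapses from its random
initial value as domains coarsen, while the tile-occupied fraction of the
line `phi` rises above its random-overlap baseline as tiles accumulate at
the remaining boundary (a three-replicate average; `phi` fluctuates until
more replicates or later times are averaged).

The same functionality is exposed on the command line
(`lineactant simulate|analyze|calibrate|adsorb|fitprofile|synth`), e.g.

```bash
lineactant adsorb predict --design 12x --sigma 0.30
lineactant calibrate --dg-dc -0.8 --dg-st 1.9
```

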