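# porinflux

Analysis tools for small-molecule permeation through bacterial porin
channels (OmpF-like β-barrels).  Given (a) conformer ensembles of a
candidate permeant and (b) free-energy surfaces of its passage through the
pore, `porinflux` computes the molecular descriptors that govern
permeation, reduces 2D free-energy surfaces to 1D profiles along the
diffusion axis, and predicts translocation currents, saturation and dwell
times.  It is aimed at computational chemists screening antibiotic or
β-lactamase-inhibitor scaffolds for outer-membrane penetration.

## What it computes

**Descriptors** — for each conformer, the minimal projection area
(MPA, Ų): the smallest area of the union of the atoms' van-der-Waals
disks projected on a plane, minimized over directions; the minimum radius

    Rmin = sqrt(MPA / π)

comparable directly to the pore's probe-accessible radius profile; the
electric dipole μ = Σᵢ qᵢ(rᵢ − r₀) (Debye) and its transversal component
in the MPA plane — the component that can align with the strong transversal
electric field of the pore constriction.

**Free-energy profiles** — a 2D surface F(CV1, z) (orientation × position
along the pore axis) is Boltzmann-averaged over CV1,

    F₁D(z) = −kT ln ∫ exp(−F(cv1, z)/kT) dcv1,

then referenced so the bulk plateaus average zero; barriers and affinity
wells are extracted automatically.

**Transport** — from F₁D(z) with an effective diffusion constant D
(default 1 nm²/ns), the low-concentration permeability is the
Kramers-type integral

    P = D σ_ref γ / ∫ exp(F(z)/kT) dz,

cross-checked against a finite-difference steady-state Smoluchowski
solver.  Saturation is described by a single-occupancy two-state Markov
model built from the mean first-passage time out of the deepest channel
well and diffusive splitting probabilities: the saturated current is
Imax(cis→trans) = koff_trans, the half-saturation concentration
K_half = (koff_cis + koff_trans)/kon_cis, and the dwell time is
τ_b = 1/(koff_trans + koff_cis).

A seeded synthetic-data module generates conformer ensembles and 2D
surfaces with analytic ground truth, so the whole chain is testable
without external trajectories.

## Worked example

```sh
python examples/03_currents_and_saturation.py
```

```text
profile                        I(1 µM) /s    Imax /s   K_half M    tau_b s
A (barrier 4.5)                       9.9   2.36e+07       2.39   1.34e-12
B (barrier 3.5)                      45.7   9.79e+07       2.14   1.47e-12
C (barrier 2.5 + well 6.0)            352   1.47e+07     0.0416    6.8e-08
```

Three profiles with decreasing central barriers (A > B > C, kcal/mol),
where only C carries a 6 kcal/mol affinity well.  The low-concentration
current follows the barrier ordering (C > B > A, every ~1 kcal/mol of
barrier costs roughly a factor e^{1/kT} ≈ 5 in current); the affinity well
in C slows the escape from the channel (dwell time τ_b ≈ 68 ns vs ~1 ps)
so its current saturates at a ~50× lower concentration (K_half ≈ 42 mM).
The other examples cover conformer descriptors (`01`), 2D→1D
marginalization (`02`) and the end-to-end pipeline (`04`); the same stages
are exposed on the command line via `porinflux gen | descriptors |
fes-marginalize | current | compare | demo`.

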