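# nucleomc

Coarse-grained, excluded-volume Monte Carlo model of how chromosomal DNA and
ribosomes organize inside a rapidly growing rod-shaped bacterium, together
with the quantitative observables, synthetic fluorescence imaging and
single-particle-tracking analyses needed to compare the model against
microscopy readouts.

## The scientific problem

In fast-growing *E. coli* the chromosomal DNA (the *nucleoid*) and the
translating ribosomes are strongly segregated: 70S-polysomes concentrate in
the polar endcaps and other DNA-poor regions, while free 30S/50S subunits
penetrate the nucleoid. `nucleomc` implements a minimal physical explanation
of this organization: **hard-core excluded volume plus entropy, and nothing
else**.

The model cell is a spherocylinder (radius 350 nm, pole-to-pole length
3.0 µm). Inside it live:

* **DNA** — a hyperbranched bead–rod polymer: a closed ring backbone with
  random side branches, 7000 plectoneme rods for two chromosome equivalents.
  Each rod vertex carries a small *red* bead (DNA–DNA excluded volume) and a
  co-located large *gray* bead that is invisible to DNA but excludes
  ribosomal particles (it stands in for the plectoneme volume a ribosome
  cannot enter).
* **Ribosomes** — either 20,000 70S particles as freely jointed 13-mer
  polysome chains (1538 complete chains), or, after dissociation, 20,000
  free 30S + 20,000 free 50S spheres of equal total volume.

There are no attractive interactions. The athermal Metropolis engine
(`nucleomc.engine`) accepts any symmetric-proposal move that creates no
overlap, no wall crossing and no bond-length change, so long runs sample the
maximum-entropy state of the composite system. In that state 70S-polysomes
and DNA demix almost completely; converting the polysomes into free subunits
makes the components mix and the nucleoid expand — each 13-mer becomes 26
independent particles demanding translational entropy.

The analysis layer measures what a microscope would:

* **Nucleoid metrics** — axial/transverse projections; nucleoid length
  `L_DNA` and width `W_DNA` as the *outside* full width at half maximum of
  the projected density; peak-to-valley contrast of bimodal linescans.
* **Imaging** — widefield rendering with a Gaussian PSF (FWHM = λ/2 =
  260 nm at λ = 520 nm) and PALM-style localization tables with ~30 nm
  localization error.
* **Tracking** — Brownian trajectories with geometric bleaching (mean 10
  frames), MSD(τ), per-trajectory estimates `D_i = msd_i(τ)/4τ`, a
  gamma-mixture two-population decomposition of the `D_i` histogram,
  trajectory aspect ratios, and first-passage times to an absorbing
  boundary (e.g. a nascent mRNA escaping to the ribosome-rich periphery).

## Worked example

Simulate a half-length cell with volume-fraction-preserving particle counts,
once with polysomes and once dissociated, and compare:

```python
from nucleomc import Spherocylinder, build_dna, build_polysomes, dissociate
from nucleomc import observables as obs
from nucleomc.engine import SimulationState, MoveSchedule, run
from nucleomc.system import merge_systems

sc = Spherocylinder(350.0, 1500.0)
dna = build_dna(sc, n_rods=3205, seed=11)
ps = build_polysomes(9157, 13, sc, seed=12, dna=dna)

poly = SimulationState(merge_systems(dna.system, ps.system).copy(), sc, seed=13)
res_p = run(poly, n_sweeps=1000, thin=100, schedule=MoveSchedule(burn_in=100))

sub = dissociate(ps, sc, dna, seed=12)
diss = SimulationState(merge_systems(dna.system, sub), sc, seed=13)
res_d = run(diss, n_sweeps=1000, thin=100, schedule=MoveSchedule(burn_in=100))

for name, sys_, res, species in (
    ("polysome", poly.system, res_p, ["r70S"]),
    ("dissociated", diss.system, res_d, ["r30S", "r50S"]),
):
    import numpy as np
    red = sys_.indices_of("dna_red")
    ribo = np.concatenate([sys_.indices_of(s) for s in species])
    env = obs.nucleoid_envelope(sys_.pos[red], sc)
    rep = obs.segregation_report(sys_.pos[ribo], sys_.pos[red], env, sc)
    print(name, round(res.report["l_dna"].iloc[-1]), 
          round(rep.fraction_inside_envelope, 3), round(rep.axial_overlap, 3))
```

Output:

```
polysome 764 0.005 0.583
dissociated 846 0.029 0.702
```

Read: with polysomes the nucleoid is axially compact (`L_DNA` ≈ 764 nm) and
only 0.5% of 70S beads sit inside the half-max nucleoid envelope — strong
segregation. After dissociation the DNA–ribosome axial overlap rises
(0.58 → 0.70), subunits penetrate the envelope several-fold more, and the
nucleoid lengthens (`L_DNA` ≈ 846 nm) — mixing and expansion, with the DNA
still avoiding the wall.

A command-line interface wraps the same workflows
(`nucleomc build | run | analyze | image | track | report | fixtures`); see
`nucleomc --help`.

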