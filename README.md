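# hrpqct

Analysis pipeline for high-resolution peripheral quantitative computed
tomography (HR-pQCT) of the distal radius and tibia: compartment
segmentation, intracortical porosity, global and subregional bone
morphometry, voxel-based linear micro-finite-element biomechanics with
pore-occlusion differentials, longitudinal common-region registration,
and treatment-response statistics.

It is written for researchers who analyze in vivo bone-microarchitecture
scans (82 µm isotropic voxels, ~9 mm axial stacks) and who need the full
analysis chain as reusable, tested code.  Because patient scans cannot be
redistributed, the package ships a synthetic phantom generator that
emulates distal radius/tibia cross-sections with voxel-counted ground
truth, so every stage of the chain is validated against known answers.

## What it computes

**Segmentation.** A closed periosteal contour per slice (edge finding at
the half-maximum level after Gaussian smoothing); the mineralized cortex
by both the standard route (3D Gaussian, fixed threshold at 16% of the
grayscale range) and an extended dual-threshold autocontour whose
endosteal boundary stays closed across pores; the trabecular structure by
a Laplace–Hamming filter and a fixed 40% threshold; and intracortical
pores by 2D component labeling (enclosed void regions per slice) followed
by 3D region growing along the scan axis.

**Morphometry.** Densities (Tot.vBMD, Ct.vBMD, Tb.vBMD, mg HA/cm³);
BV/TV derived densitometrically as Tb.vBMD / 1200 mg HA/cm³; Tb.N from
the mean 3D spacing of the trabecular mid-axes, with Tb.Th = BV/TV / Tb.N
and Tb.Sp = (1 − BV/TV) / Tb.N by plate-model assumptions; annular
cortical thickness Ct.Th = Ct.Ar / periosteal perimeter; direct
maximal-sphere thickness Ct.Th\* on the pore-filled cortex; intracortical
porosity Ct.Po = 100·Ct.PoV / (Ct.PoV + Ct.BV); all indices also per
subregion (inner/outer concentric split holding 60% of the trabecular
area, × four anatomical quadrants).

**Micro-FE.** One 8-node brick element per bone voxel, E = 10 GPa,
ν = 0.3, homogeneous; uniaxial 1% apparent compression with lateral-free
end faces; stiffness K, apparent modulus E, Pistoia failure load F (2% of
tissue beyond 0.7% energy-equivalent strain), and the cortical load
fraction Ct.LF at the distal boundary.  A second solve with pores
digitally occluded yields ΔK_PO, ΔE_PO, ΔF_PO (percent of original) and
ΔCt.LF_PO (absolute).

**Longitudinal.** Common volume of interest between visits by slice-wise
periosteal-area cross-correlation; percent change from baseline; Spearman
response-correlation tables with the conventional star notation.

## Worked example

```python
from hrpqct import (PhantomSpec, PoreModel, TrabecularLattice,
                    generate_phantom, segment_all, compute_morphometry)
from hrpqct.microfe import pore_occlusion_experiment

spec = PhantomSpec(n_slices=16, outer_radius_mm=4.0, cortical_thickness_mm=0.9,
                   trabecular_lattice=TrabecularLattice(0.6, 0.10),
                   pore_model=PoreModel(30, 0.12, 0.8), seed=3)
vol, truth = generate_phantom(spec)
masks = segment_all(vol)
rec = compute_morphometry(vol, masks)
po = pore_occlusion_experiment(masks, vol.voxel_mm)
```

prints (via the formatting in the example script):

```
Ct.Po     6.75 %    (truth 5.09 %)
Tb.N      1.75 1/mm (truth 1.67 1/mm)
Ct.Th*   1.044 mm  (truth 0.900 mm)
BV/TV    0.177      (voxel-counted 0.204)
Tb.vBMD  212.6 mg HA/cm^3
K       179.44 kN/mm   E_app  4.66 GPa
F_fail   1.358 kN     Ct.LF 0.880
dK_PO     6.53 %      dCt.LF_PO +0.0073
```

Reading these numbers: trabecular number is recovered within 5% of the
lattice truth and the direct cortical thickness within two voxels.
Densitometric BV/TV (0.177) sits below the voxel-counted truth (0.204)
because the phantom's tissue density (1100) is below the compact-bone
constant (1200) — a deliberate, documented bias of the densitometric
derivation.  Porosity on this phantom overshoots its truth because
sub-threshold voxels at rod–cortex junctions are claimed as pores; the
enclosed-pore annulus phantom, where no such junctions exist, recovers
Ct.Po within 10% (see the test suite).  Occluding the ~5% porosity
recovers 6.5% stiffness and shifts 0.7 percentage points of the distal
load onto the cortex.

A command-line interface mirrors the library:
`hrpqct phantom make`, `hrpqct segment`, `hrpqct morpho`, `hrpqct
register`, `hrpqct fe --occlude-pores`, `hrpqct stats`, and `hrpqct run`
for the full longitudinal chain on a scan pair.

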