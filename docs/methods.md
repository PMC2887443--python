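# Methods

`sterolorder` quantifies the lateral spatial and orientational organization
of sterols in fluid phospholipid leaflets: how strongly sterols avoid direct
contact and accumulate in the second coordination shell, whether their
neighbors arrange with three-fold (cholesterol-like) or two-fold
(flat-sterol-like) symmetry around the molecular frame, how first-shell
phospholipids orient their acyl chains relative to a sterol, and which
relative orientations proximal sterol pairs prefer. This note records the
models, conventions, parameters and numerical choices behind each statistic,
and what the synthetic-data tests do and do not demonstrate.

## The sterol molecular frame

A sterol's ring system is flat on one side (the alpha face) and carries two
off-plane methyl groups (C18 on C13, C19 on C10) on the other (the beta
face). The package anchors a right-handed orthonormal frame on each sterol:

- origin at C13;
- `e_x = unit(C18 - C13)` — toward the rough beta face;
- `e_z` = the component of `C10 - C13` orthogonal to `e_x` (up the ring
  axis), so the xz-plane contains C13->C10;
- `e_y = e_z × e_x`, splitting the beta face into beta1 (y > 0) and beta2
  (y < 0).

The absolute chirality of the beta1/beta2 labels cannot be pinned down from
a printed map alone, so `build_sterol_frame(..., mirror=True)` flips `e_y`
for comparison with mirrored conventions. For the flat sterol analogue
(`DCHL`, cholesterol minus C18/C19) the missing methyl position is
reconstructed assuming ideal sp3 geometry at C13: the C18 direction opposes
the sum of unit bond vectors to C12, C14 and C17, with a standard C-C bond
length of 0.153 nm (the bond length only scales the reconstructed point, not
the frame).

In-plane angles phi are measured from `+x`, anticlockwise, in [0, 360).
Eight angular sectors partition the circle: NE [22.5, 67.5), N [67.5,
122.5), NW [122.5, 157.5), W [157.5, 202.5), SW [202.5, 247.5), S [247.5,
292.5), SE [292.5, 337.5), E [337.5, 22.5) (wrapping through zero). The
printed NW range spans 35 degrees while the others span 45; the list is used
verbatim because it tiles the circle gap-free. Intervals are half-open and
an exact boundary value belongs to the anticlockwise-later sector. The
sectors that host the three-fold sterol motif are W (alpha), NE (beta1) and
SE (beta2).

## Lateral pair correlation and coordination shells

`lateral_rdf` computes g(r) from the in-plane (x, y) minimum-image distance
between molecular centers of mass within one leaflet:

    g(r) = <pairs in annulus> / (annulus area × mean target density),

pooled over frames and leaflets, with the reference molecule excluded from
its own target set for like-species pairs. Centers of mass are mass-weighted
(united-atom masses) over the whole molecule by default; a ring-only mode
and a 3D-distance mode exist for comparison. Normalization is per leaflet
(each leaflet contributes its own density), because every downstream
statistic is single-leaflet.

Error bars are Monte-Carlo standard errors per bin: unordered pair counts of
a homogeneous process are Poisson, and like-species histograms count each
unordered pair twice, which doubles the count variance — hence
`sigma = sqrt(2 × expected count) / norm` for like pairs and
`sqrt(expected count) / norm` for cross pairs. This model was verified
against the empirical frame-to-frame variance of CSR configurations.

Coordination shells default to 0.4–0.8 nm (first) and 0.8–1.1 nm (second);
the second shell is capped at 1.1 nm to exclude third-shell contributions.
`shell_density_ratio` reports the target density inside each shell relative
to the leaflet mean; it equals the annulus-area-weighted average of g(r)
over the shell exactly when bin edges align (unit-tested at 1e-9). Defaults:
bin width 0.01 nm (fine enough to resolve ~0.05 nm-spaced sub-peaks in
structured first shells), r_max 2.5 nm, truncated with a warning at half the
smallest lateral box length.

## Molecular-frame density maps

`accumulate_density_map` histograms, for every reference sterol, the
frame-projected positions of selected target atoms: the lab-frame
minimum-image displacement from the frame origin is computed first, then
rotated into the molecular frame and projected on (x, y). Maps are total
densities (atoms nm^-2 per reference per frame), not probability densities,
so a spatially random field of density rho reads ~rho everywhere. No cut is
applied along frame z (full projection); `frame_z_range` restricts it if
wanted. The map integral equals the mean in-window atom count per reference
per frame (conservation, tested at 1e-9).

Target selections: `ring` (the ring-atom selection below), `chains` (all
united-atom acyl carbons of both chains — multiple ~0.5 nm-spaced
coordination shells require whole-chain density, with `terminal_methyls` as
the narrower alternative), and `ring_com`/`com` (one point per molecule).
The ring selection is 15 shared ring carbons (C1–C14, C17) plus, for
cholesterol, the two off-plane methyls: 17 atoms for cholesterol, 15 for the
flat analogue. This reading is forced by requiring the frame atom C18 to be
part of the cholesterol selection while the flat sterol differs only by the
two methyls.

Defaults: extent 2.5 nm, bin 0.05 nm. `find_peaks` takes local maxima
(3×3 neighborhood) above `threshold × mean`, where the mean is taken over
the searched radial band when one is given — with a motif-structured map the
full-map mean is dominated by empty background and would let single-count
Poisson fluctuations through. Peaks are greedily pruned highest-first by a
minimum Euclidean separation (default 0.2 nm) and annotated with phi, r and
sector.

## Co-localization angles

A phospholipid is in a sterol's first coordination shell when at least one
acyl-chain center of mass lies within 0.75 nm (lateral minimum image) of the
sterol anchor. For each such pair, theta is the in-plane angle between the
chain–chain vector (sn-1 COM -> sn-2 COM) and the vector from the sterol
anchor to the chain midpoint. Chains are equivalent, so theta is folded to
theta90 = 90 − |90 − theta|: 0 = collinear, 45 = diagonal, 90 = 'facing'
(both chains equidistant — the sandwich geometry). The sterol anchor is the
ring COM by default (`anchor="molecule"` uses the whole molecule; both
conventions are defensible and the difference is small for tail-less
sterols). Angles use in-plane projections (`planar=False` gives the 3D
variant). Histograms default to 5-degree bins; the sector-resolved variant
bins pairs by the chain midpoint's sector in the sterol frame, and sector
counts sum exactly to the total.

## Sterol pair orientations

The in-plane orientation of a sterol is the lab-xy projection of its C6->C11
vector. For every ordered pair (central, neighbor) with the neighbor's ring
COM inside the second shell (0.8–1.1 nm on the frame-projected radius;
`mode="lab"` uses the lab-lateral radius), the signed anticlockwise angle
from the central to the neighbor orientation vector, in [0, 360), is binned
into the neighbor's sector distribution. Each unordered pair contributes
twice — once per choice of central molecule — so totals are even, and a
consequence worth knowing: a pair with orientation offset delta appears once
at angle delta (in the sector where the central sees the neighbor) and once
at −delta (where the neighbor sees the central). Only for anti-aligned pairs
(delta = 180) do both contributions land in the same sector. In recovery
tests with von Mises offsets (mu = 120, kappa = 8) the reverse-tail
contamination of the target sector biases its circular mean upward by about
+2 degrees; the recovery checks measure the estimator as defined, bias
included.

## Synthetic leaflet generator

The generator emulates single leaflets (or mirrored bilayers) of mixed
sterol/phosphatidylcholine composition with known ground truth. Molecules
are rigid idealized templates placed upright (zero tilt) and rotated about
the lab z only, so the molecular xy-plane coincides with the lab plane and
placement geometry predicts every statistic. Template coordinates are
constraint-driven, not a force field: C13/C18/C10/C6/C11 satisfy the frame
invariants exactly; the three ring neighbors of C13 are arranged so the flat
sterol's tetrahedral reconstruction reproduces the cholesterol C18 direction
exactly; each template is laterally centered on its ring centroid, making
frame origin, ring COM and whole-molecule COM agree to < 0.01 nm (placement
errors stay well under one 0.05 nm map bin). The PC template has two
straight 18-carbon chains 0.70 nm apart (inside the realistic 0.55–0.85 nm
range) under a headgroup anchor.

Defaults emulate the reference composition: 128 PCs + 32 sterols (20 mol%)
in a box of lateral area 39.90 nm^2; `mole_fraction_to_counts` converts
fractions (round(n·f/(1−f))) and `REFERENCE_COMPOSITIONS` carries the reference
sterol counts (14, 32, 56, 86, 122 per 128 PCs) verbatim. Ordering modes:

- `csr` — uniform positions and orientations (the homogeneity null);
- `hard_disk` — dart throwing with a minimum center separation (default
  0.45 nm), bounded attempts, `PackingError` with the achieved count on
  failure;
- `triangular` — seed sterols with up to three second-shell neighbors at
  frame angles {180, 45, 315} (the W/NE/SE motif) at the set spacing
  (default 1.0 nm) with Gaussian angular (5 degrees SD) and radial (0.02 nm
  SD) jitter;
- `linear` — neighbors at {0, 180}: the two-fold flat-sterol motif.

Motif neighbor orientations default to anti-aligned (offset 180), the one
choice under which both members of a pair see each other at the same frame
angle, so density-map recovery is exact; fixed, von Mises and uniform rules
are available. Motif clusters are dart-thrown with a center exclusion of
3.3 × spacing so that no inter-cluster sterol pair can enter the 0.8–1.2 nm
peak-search band — peak counts then reflect the motif alone. Optional
first-shell lipids sit at preferred frame angles (default five, evenly
spread) at 0.55 nm midpoint radius with a controlled co-localization angle
(default 'facing', 90 degrees). Frames are independent redraws from one
seeded `numpy` Generator stream; identical parameters + seed reproduce
byte-identical output files. The `GroundTruth` record (JSON sidecar) stores
every placement position, orientation, leaflet, pair angle/distance/offset
and lipid angle/radius/theta; recovery tests consume only this record.

What the generator does *not* emulate — and hence what passing tests do not
show about real trajectories: sterol tilt (frames are never inclined, so
frame-projected and lab-lateral radii coincide by construction), chain
conformational disorder (chain COMs have zero spread), thermal breakup of
motifs beyond Gaussian jitter, density correlations between shells, and
leaflet interdigitation. Analyses on real coordinate data exercise exactly
the same code paths, but their statistical behavior (peak widths, shell
mixing) will differ.

## Numerical and design choices

- Units: nm internally everywhere; PDB Angstrom converted on read; masses in
  amu (united atoms: CH 13.019, CH2 14.027, CH3 15.035).
- Molecules are made whole on read by nearest-image chaining along the
  file's atom order; all COMs use unwrapped coordinates.
- Leaflet midplane = mass-weighted z-centroid of all lipid atoms per frame;
  anchors exactly on the midplane label as upper. Per-frame assignment, no
  flip-flop tracking.
- Atom-name matching is exact and case-sensitive after whitespace strip;
  per-species alias tables are honored.
- Degenerate geometry (coincident frame atoms, C10 collinear with C13–C18,
  zero-sum reconstruction neighbors, zero-length projected vectors) raises
  `DegenerateGeometryError` at a 1e-9 vector-norm threshold rather than
  returning arbitrary axes.
- Histogram bins are half-open `[lo, hi)` with the top bin closed; angular
  values constructed exactly on a bin edge (e.g. a noiseless 180-degree
  offset) may split across the adjacent bins by float rounding — tests treat
  that as the documented behavior.
- theta90 = 90 (exact facing) belongs to the top bin by the closed-top rule.
- CSR-null statistical checks run at 0.05 nm bins (34 bins across
  0.3–2.0 nm) so a 3-sigma-per-bin band has a small family-wise false-alarm
  rate; at the 0.01 nm profile default the same band spans 170 bins and the
  expected extreme deviate alone reaches ~3.2 sigma.
- Problem sizes in tests and in `scripts/acceptance.py` (250 molecules ×
  200 frames for the null; 40–100 sterols × 50 frames for recoveries) were
  chosen to put sampling errors well inside the asserted tolerances.

## Known limitations

- Only orthorhombic boxes; binary trajectory formats (XTC/TRR/DCD) are not
  read — an adapter just needs to yield one Universe per frame to
  `snapshot_from_universe`.
- The sterol templates carry no flexible tail; whole-molecule and ring COMs
  nearly coincide, which underestimates the difference between the two
  anchor conventions compared with real cholesterol.
- `min_image_shift` assumes displacements within one box image per axis
  beyond the nearest (standard minimum-image), which is always satisfied for
  in-box coordinates.
- Sterol tilt analysis relative to the membrane normal is out of scope.
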