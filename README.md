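# sterolorder

Lateral spatial and orientational order statistics for sterol/phospholipid
membrane leaflets.

Cholesterol makes fluid phospholipid membranes liquid-ordered and underlies
raft formation, yet the relevant structure is local: sterols avoid direct
sterol–sterol contact, sit preferentially in the second coordination shell
(~1 nm), and arrange around each other with a symmetry dictated by the two
off-plane methyl groups (C18/C19) on the rough beta face of the ring system.
`sterolorder` is a Python package for membrane simulators and structural
bioinformaticians that measures this organization in coordinate snapshots
(GRO/PDB) of mixed sterol/phosphatidylcholine leaflets:

- **Lateral pair correlation** `g(r)` and **coordination-shell occupancies**
  — the in-plane neighbor density around each sterol center of mass relative
  to the leaflet mean, with shells at 0.4–0.8 nm (first) and 0.8–1.1 nm
  (second),

      g(r) = ⟨pairs in annulus⟩ / (2πr Δr · ρ̄),   per leaflet.

- **Molecular-frame 2D density maps** — neighbor atoms histogrammed in the
  per-sterol frame (origin C13, x along C13→C18, xz-plane through C10),
  separating the smooth alpha face (x < 0) from the beta1 (y > 0) and beta2
  (y < 0) sub-faces, with peak extraction over a radial band and the eight
  angular sectors NE, N, NW, W, SW, S, SE, E.

- **Co-localization angles** — for phospholipids with a chain center of mass
  within 0.75 nm of a sterol, the folded angle θ₉₀ = 90° − |90° − θ| between
  the sn-1→sn-2 chain axis and the sterol→midpoint vector (0° collinear,
  90° 'facing').

- **Sterol pair orientations** — sector-resolved distributions of the signed
  angle between the C6→C11 vectors of second-shell sterol pairs.

- A **synthetic leaflet generator** (`csr`, `hard_disk`, `triangular`,
  `linear` modes) with a recorded ground truth, so every analysis is
  exercisable and testable without molecular-dynamics input.

## Worked example

Generate a leaflet of 40 sterols carrying the three-fold neighbor motif
(second-shell neighbors at frame angles 180°/45°/315°, spacing 1.0 nm,
5° jitter) and recover it:

```yaml
# run.yaml
input:
  generate:
    mode: triangular
    n_sterols: 40
    n_lipids: 0
    box: [20.0, 20.0, 6.0]
    n_frames: 50
    spacing: 1.0
    angular_jitter_deg: 5.0
analyses:
  shells: {}
  densmap: {role: ring_com, figure: false}
output_dir: out
seed: 11
```

```sh
sterolorder all --config run.yaml
```

`out/summary.json` then contains (values printed by this exact run):

```json
"shells":  {"ranges_nm": [[0.4, 0.8], [0.8, 1.1]],
            "ratios": [0.0, 8.597087524280163]},
"densmap": {"peaks": [
  {"phi_deg": 47.05,  "r_nm": 0.991, "sector": "NE", "height": 35.2},
  {"phi_deg": 312.95, "r_nm": 0.991, "sector": "SE", "height": 32.4},
  {"phi_deg": 178.60, "r_nm": 1.025, "sector": "W",  "height": 22.8}]}
```

Read: the first coordination shell holds no sterols at all (ratio 0.0) while
the second shell is 8.6× enriched over the leaflet mean — sterols avoid
contact and crowd the ~1 nm shell. The frame-density map shows exactly three
peaks, one per face (alpha → W, beta1 → NE, beta2 → SE), each within one bin
(0.05 nm / 5°) of the generator's set positions at r = 1.0 nm: the
three-fold motif is recovered from coordinates alone. The same pipeline runs
on real trajectories by replacing `generate` with `paths: [traj0.gro, ...]`.

The library API mirrors the subcommands: `lateral_rdf`,
`shell_density_ratio`, `accumulate_density_map`, `find_peaks`,
`theta90_distribution`, `sector_orientation_distributions`,
`generate_leaflet`, `read_snapshots` / `write_snapshots`. See
`docs/methods.md` for models, conventions and parameter rationale.

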