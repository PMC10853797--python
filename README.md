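# spooltrace

Spiral genome tracing for double-stranded DNA viruses: generate
coarse-grained DNA spirals (one pseudoatom per base pair), fit them to
cryo-EM density maps by a summed fitting energy, scan spiral parameters to
locate winding shells, upgrade optimal traces to all-atom B-DNA models, and
evaluate the analytic capsid-geometry quantization formulas for multi-start
("points of entry") DNA spooling.

## What it does

- **`spooltrace.spiral`** — spherical spirals (`theta = p/(2*pi*r) *
  (phi - phi0)`, constant great-circle pitch) and cylindrical spirals
  (`z = p/(2*pi) * (phi - phi0)`), multi-start families, harmonic radius
  modulation, equal arc-length pseudoatom placement (default 0.34 nm/bp).
- **`spooltrace.density`** — MRC/CCP4 2014 map I/O (axis permutations
  normalized, Angstrom on disk, nm internally), trilinear interpolation,
  the fitting energy `E = -sum(rho)` (lower = better fit), and a
  Gaussian-splat synthetic map generator for planted-spiral testing.
- **`spooltrace.scan`** — systematic one-parameter grid scans, coordinate
  descent cycling several scans, and shell detection as prominence-filtered
  local minima of the energy-vs-radius curve.
- **`spooltrace.atomistic`** — all-atom duplex building by rigid placement
  of idealized Watson-Crick base-pair templates along rotation-minimizing
  frames with explicit twist (default 36 deg/bp); inter-residue O3'-P bond
  strain report (replacing force-field annealing); PDB v3.3 / mmCIF output
  (traces as one MG ion per base pair).
- **`spooltrace.capsid`** — closed-form packing geometry: DNA slope
  `atan(p/(2*pi*r))`, intrashell `(p/n_pe)*cos(theta_s)` and intershell
  `sqrt((d_intra/2)^2 + dr^2)` interhelical distances, hexagonal-packing
  offset `360/(2*n_pe)`, dome turn counts `n_pe/2` and `(n_pe-2)/2`,
  minimum `n_pe`-conserving radius, portal/funnel and capsid inner-diameter
  quantization in the two integers `(n_pe, n_s)`.

## CLI

All angles are degrees and lengths nm at the CLI. A plain-text
`key = value` config file can supply defaults (`--config`); flags override.

```sh
# coarse-grained trace (PDB with MG pseudoatoms, or .txt)
spooltrace trace --geometry cylindrical --r 18.84 --p 25.1 --h 50 \
    --n-entries 10 -o shell1.pdb

# synthetic planted-spiral map
spooltrace synthmap --geometry cylindrical --r 10 --p 8 --h 12 \
    --noise-sd 0.33 --seed 7 -o planted.mrc

# grid scan of one parameter; CSV + best value
spooltrace scan --geometry cylindrical --r 10 --p 8 --h 12 \
    --map planted.mrc --plan r:8:12:0.1 -o scan_r.csv

# coordinate descent over several plans
spooltrace descend --geometry cylindrical --r 9 --p 8 --h 12 \
    --map planted.mrc --plan r:8:12:0.1 --plan phi0:0:358:2 -o trail.csv

# shell detection from the energy-vs-r curve
spooltrace shells --geometry cylindrical --r 4 --p 2.5 --h 6 \
    --map map.mrc --r-lo 3 --r-hi 22 -o shells.csv

# all-atom model along a spiral (optionally with a FASTA sequence)
spooltrace build --geometry cylindrical --r 10 --p 8 --h 12 \
    --sequence-fasta genome.fa -o model.cif

# analytic capsid geometry
spooltrace capsid --mode dome-turns --n-pe 10
spooltrace capsid --mode survey -o diameters.csv
```

## Notes

- The DNA slope is implemented as `atan(p/(2*pi*r))` — the rise of one turn
  over its circumference. This is the form consistent with a 12 degree
  slope and a 2.46 nm intrashell distance at `p = 25.1` nm, `n_pe = 10`.
- Base-pair templates (`src/spooltrace/data/bp_templates.csv`) are built by
  `scripts/make_bp_templates.py` from CCD ideal nucleotide coordinates
  placed in a standard base-pair reference frame, with glycosidic/backbone
  torsions tuned so straight-helix concatenation gives a 1.60 Angstrom
  inter-residue O3'-P distance.
- Out of scope: force-field minimization, semiflexible fitting of
  connector/turnaround segments, conformer (NtC) assignment, and refits of
  experimental maps (replaced by synthetic planted-parameter recovery).
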