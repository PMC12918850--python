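# fibrilfold

Tools for comparing amyloid protofilament folds and analysing in-vitro
fibrillization kinetics, aimed at structural biologists classifying
patient-derived tau (and other amyloid) filament structures.

Cryo-EM structures of tau filaments extracted from post-mortem brain show
that each tauopathy is associated with characteristic protofilament folds.
Two folds can be globally different yet share locally conserved motifs whose
relative orientation has rotated — a global superposition hides exactly the
similarity one wants to detect. `fibrilfold` implements a *local* comparison:

- **All-window superposed RMSD.** Given two single-rung folds and a residue
  correspondence (by canonical 2N4R residue number, or by Needleman–Wunsch
  sequence alignment when numbering schemes differ), every contiguous window
  of paired residues with length ≥ `min_window` is *independently* superposed
  by the Kabsch algorithm (proper rotations only) and its Cα (or backbone)
  RMSD recorded:

  `RMSD(s, w) = min over rigid motions (R, t), det R = +1 of
  sqrt( (1/n) Σᵢ ‖xᵢ − (R yᵢ + t)‖² )` for the window starting at
  position `s` with length `w`.

  Windows never cross correspondence gaps (splicing differences, chain
  breaks). The **localized RMSD** summary is the unweighted mean over all
  windows; a fold library is ranked by it, and the full matrix is rendered
  as a triangular heat-map (window start vs. window length).

- **Synthetic helical filaments.** A filament is rung 0 repeated with rise
  `h` (Å/rung, ~4.8 Å cross-β spacing) and signed twist `ω` (deg/rung,
  negative = left-handed), related to the crossover distance by
  `crossover = 180° · h / |ω|`. Builders stack a rung into an ideal helix,
  apply smooth cosine-tapered local deformations (ground truth for
  localization tests), and recover `h`, `ω` and the crossover from
  coordinates.

- **ThT kinetics.** Thioflavin-T plate-reader curves are
  background-subtracted (mean of the first five readings) and fit by
  Levenberg–Marquardt to the Gompertz sigmoid
  `y(t) = A·exp(−exp(−(t − tᵢ)/B))`, giving the apparent elongation rate
  `k_app = 1/B`, the half-time `t½ = tᵢ − B·ln(ln 2)` and the aggregation
  propensity `1/t½`. QC discards wells with max raw RFU < 50 or fit MSE
  above one standard deviation of the per-well signal maxima in the
  condition group. A seeded simulator generates replicate wells on the
  standard 5-min/24-h design for parameter-recovery studies.

## Worked example

```python
import fibrilfold as ff

rung = ff.make_serpentine_rung()                 # synthetic rung, residues 273-372
mutant = ff.perturb_region(rung, (313, 333), 3.0, seed=7)

summary = ff.compare_folds(rung, mutant)
print(f"localized RMSD: {summary.localized_rmsd:.3f} A over {len(summary.matrix)} windows")
print(f"R3 hairpin (312-334): {summary.motif_rmsd['R3_hairpin']:.3f} A")
print(f"cofactor site (290-311): {summary.motif_rmsd['cofactor_site']:.3f} A")

params = ff.HelicalParams(4.8, ff.crossover_to_twist(600.0, 4.8, "left"))
est = ff.estimate_helical_params(ff.build_filament(rung, params, 9))
print(f"rise {est.rise:.3f} A, twist {est.twist:.3f} deg/rung, crossover {est.crossover:.1f} A")

curves = ff.simulate_tht(A=100, t_i=10, B=2, noise_sd=2.0, n_replicates=9, seed=1)
f = ff.fit_gompertz(ff.subtract_background(curves[0]))
print(f"A={f.A:.1f} RFU, t_i={f.t_i:.2f} h, B={f.B:.2f} h, "
      f"k_app={f.k_app:.3f} /h, t_half={f.t_half:.2f} h")
```

prints

```
localized RMSD: 0.514 A over 4851 windows
R3 hairpin (312-334): 1.070 A
cofactor site (290-311): 0.000 A
rise 4.800 A, twist -1.440 deg/rung, crossover 600.0 A
A=100.6 RFU, t_i=9.94 h, B=1.99 h, k_app=0.503 /h, t_half=10.67 h
```

The deformation put a 3 Å bump on residues 313–333, so the R3-hairpin motif
shows ~1 Å RMSD while the untouched cofactor site stays at zero; the
localized RMSD averages clean and perturbed windows. The helical round trip
recovers the build parameters exactly, and the Gompertz fit recovers the
simulated kinetics to within the 2% injected noise.

The same operations are available from the shell:

```bash
fibrilfold build rung.pdb --rise 4.8 --crossover 600 --rungs 9
fibrilfold compare typeI.cif typeII.cif --atoms CA --min-window 3
fibrilfold heatmap typeI.cif typeII.cif
fibrilfold rank query.cif agd.cif cbd.cif p301t.cif
fibrilfold tht-sim --A 100 --ti 10 --B 2 --noise-sd 2 --seed 7
fibrilfold tht-fit plate.csv --layout wide --time-unit min
```

Every run writes a `run.json` provenance record; identical inputs and seeds
give byte-identical tabular outputs.

## Layout

- `src/fibrilfold/structure.py` — PDB/mmCIF I/O, rung extraction
- `src/fibrilfold/align.py` — residue correspondences (numbering / sequence)
- `src/fibrilfold/rmsd.py` — Kabsch, window matrix, localized RMSD, ranking, heat-maps
- `src/fibrilfold/builder.py` — helical fixture generator and parameter recovery
- `src/fibrilfold/kinetics.py` — ThT loading, Gompertz fitting, QC, simulator
- `src/fibrilfold/cli.py` — `fibrilfold` command-line interface
- `docs/methods.md` — models, assumptions, parameter choices, limitations
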