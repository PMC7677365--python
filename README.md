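# helixcurate

Curation tools for helical cryo-EM particle metadata, plus the
atomic-model comparison metrics used to analyse the resulting
structures.

The metadata side operates on single-loop STAR particle tables
(RELION column naming) and covers:

- **star_io** — read/write particle tables, preserving unknown columns
  verbatim; pixel- or Å-valued origin shifts are normalised to Å.
- **filament_model** — group particles into filaments, order them along
  the principal axis, flag polarity flips (psi off by ~180°) and
  off-plane tilts, and window filament traces into overlapping segment
  boxes (e.g. a 328 px box stepped by one 26 px subunit holds 12 whole
  subunit steps).
- **ctf_smooth** — per-filament defocus smoothing: for every particle,
  fit a line through a 5-neighbor window after discarding the highest
  and lowest mean defocus, and evaluate it at the particle's arc
  position.  Astigmatism (U−V) is preserved.
- **helix_params** — per-step helical rise (Å) and twist (deg) from
  refined coordinates/origins/Euler angles, dataset mean ± SD, then
  two-stage selection: remove >2×SD outliers, recompute, and keep steps
  inside a 95% confidence band on both parameters.
- **struct_metrics** — PDB/mmCIF reading (via biotite), a small
  selection language, Kabsch superposition, Cα RMSD, Shrake–Rupley SASA
  on a deterministic spiral lattice (960 dots, 1.4 Å probe, Bondi
  radii), group/buried areas, minimum group distances, mean-B
  percent differences, van der Waals clash scanning and side-chain
  rotation angles.
- **synthetic_data** — a seeded generator for filament metadata with
  known ground truth (rise/twist, planted outliers, polarity flips,
  defocus gradients and spikes) and toy screw-symmetric polymers for
  the structural metrics.

## CLI

```sh
helixcurate simulate  --out sim.star --truth truth.tsv --seed 1
helixcurate convert   --in particles.star --out particles_clean.star
helixcurate window    --trace traces.tsv --box 328 --step 26
helixcurate smooth-ctf --in particles.star --out smoothed.star --window 5
helixcurate curate    --in particles.star --out kept.star \
                      --sd-mult 2 --ci 0.95 [--expected-twist -166.7] \
                      [--origin-convention subtract|add]
helixcurate metrics rmsd|sasa|buried|dist|bfac|clash \
                      --ref X.pdb [--mobile Y.pdb] --sel "chain A and resi 373-375"
```

Selection expressions are AND-joined clauses: `chain`, `resi` (ranges),
`name`, `resn`, `sidechain`, `backbone`.

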