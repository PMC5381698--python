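# quatlock

Quaternary-structure analysis of oligomeric enzyme assemblies: point-group
symmetry detection, apo vs product-bound conformational-change profiling,
inter-subunit **lock / interlock** contact classification, substrate-induced
compaction metrics, and the supporting biophysical calculations (Matthews
coefficient, Michaelis–Menten/Hill kinetics, thermofluor melting curves).

## Who this is for

Structural biologists comparing two conformational states of a homo-oligomer
— the motivating system is octameric human UDP-glucose pyrophosphorylase
(UGP), whose eight subunits form two stacked C4 rings with overall D4
symmetry, and whose sugar-binding loop is braced by an *intermolecular*
Arg–Asp contact from the neighbouring subunit (the interlock; monomeric
relatives achieve the same stabilization *intramolecularly*, the lock).  The
package quantifies, for any such pair of structures:

* **Symmetry** — the highest-order point group Cn/Dn whose operations map
  every chain onto another chain with mean Cα residual ≤ a tolerance
  (default 1.5 Å, rotation angles within 5° of ideal).  Interfaces are typed
  `end_to_end` (contacts dominated by the named C-terminal strands on both
  sides) or `side_by_side`.
* **Displacement** — after a Kabsch superposition on a user-named stable
  region, per-residue Cα and maximum side-chain heavy-atom displacements in
  a report region, with the maxima and the residues attaining them.
* **Interlock** — typed contacts (H-bond ≤ 3.5 Å N/O donor→acceptor,
  salt bridge ≤ 4.0 Å basic-N/acidic-O, hydrophobic C–C ≤ 4.5 Å; heavy-atom,
  distance-only) touching a binding region, classified `lock` (same chain,
  ≥ 20 residues apart in sequence), `interlock` (neighbouring chain),
  `both` or `none`, with a per-chain symmetry/recurrence check and a
  side-chain-truncation mutation screen.
* **Compaction** — per-axis extents and bounding-box (or convex-hull) volume
  of both states in the symmetry frame (z = principal axis);
  `percent_volume_change = (V_holo/V_apo − 1)·100`, negative = compaction.
* **Scalar models** — unit-cell volume
  V = abc·√(1 − cos²α − cos²β − cos²γ + 2cosα·cosβ·cosγ);
  Matthews coefficient V_M = V_cell/(Z·M) and solvent content
  V_s = (1 − 1.230/V_M)·100 %; least-squares fits of v = V_max·x/(K_m + x)
  and v = V_max·x^H/(K^H + x^H) with an extra-sum-of-squares F-test between
  them; Boltzmann sigmoid melt fits F(T) = 1/(1 + exp((T_m − T)/s)).

A seeded synthetic-data module generates toy subunits, Cn/Dn assemblies,
planted contacts, hinge-deformed apo/holo pairs and noisy kinetics/melt data
with exact ground truth, so the entire pipeline is testable offline.

## Worked example

Generate a synthetic D4 octamer pair — planted Arg–Asp interlock at 2.9 Å,
10° hinge on residues 5–9, 5 % isotropic compaction — then analyse it:

```bash
quatlock simulate --seed 1 --out-dir demo --compaction 0.95
printf 'binding:\n  ranges: [[5, 9]]\nstable:\n  ranges: [[1, 4], [10, 24]]\nc-term:\n  ranges: [[24, 30]]\n' > demo/regions.yaml
quatlock report --apo demo/apo.pdb --holo demo/holo.pdb \
    --regions demo/regions.yaml --binding-region binding \
    --fit-region stable --report-region binding \
    --terminal-region c-term --out demo/report.json
```

Key numbers from `demo/report.json`:

* `symmetry.holo.point_group: "D4"` with `fit_residual: 0.0` and chain
  cycle `[[A,B,C,D],[E,F,G,H]]` — the two stacked C4 rings are recovered
  exactly.
* `interlock.classification: "interlock"`, recurring pair `[7, 27]` —
  the planted residue-7(Arg)→residue-27(Asp, neighbouring chain) contact
  recurs in all eight chains; no chain deviates.
* `compaction.percent_volume_change: -14.3` — a 0.95 linear shrink is a
  0.95³ − 1 = −14.26 % volume change, recovered by the bounding-box and
  convex-hull measures alike.
* `displacement.binding.max_ca: 0.939` Å at residue 6 — the hinge chord
  2·d·sin(5°) plus the small compaction contribution.

The scalar tools work the same way; for instance a trigonal cell
(138.97, 138.97, 311.62 Å; 90, 90, 120°) holding 24 chains of 57 kDa:

```bash
quatlock matthews --cell 138.97 138.97 311.62 90 90 120 --z 24 --mass 57000
```

prints `"matthews_vm": 3.81, "solvent_content_percent": 67.7` — a typical,
solvent-rich protein crystal.

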