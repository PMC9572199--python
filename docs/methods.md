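# Methods

This note documents the models, parameters and design choices behind
`gaginter` — what each analysis computes, why the defaults are what they
are, and what the synthetic fixtures do and do not establish.

## System model

A `MolecularSystem` is a flat list of atoms, each carrying a partition
label (`receptor`, `ligand`, `water`, `cation`, `anion`), explicit bonds,
and derived annotations. A `Trajectory` ties an ordered set of coordinate
frames (Å) with a strictly increasing time axis (ps) to one system; at the
standard 100 ps save spacing a 140 ns run stores 1400 frames.

Annotations are derived deterministically from composition:

* **Hydrophobicity** — an atom is apolar when it is carbon or sulfur and
  every bonded heavy neighbor is carbon or sulfur (a neighborless carbon
  qualifies vacuously). This is an explicit, testable stand-in for the
  fuzzier "hydrophobic atom" notion used in contact analysis.
* **Charge groups** — Arg guanidinium (+1), Lys ammonium (+1), His
  imidazolium (+1, only when a protonation flag is set), Asp/Glu
  carboxylate (−1), protein N/C termini (±1), ligand sulfate (−1) and
  carboxylate (−1), and monatomic ions (Na⁺ +1, Ca²⁺/Mg²⁺ +2, Cl⁻ −1).
  Each group has a *representative heavy atom* used for labels:
  carboxylate → its carbon, sulfate → its sulfur, an ion → itself. A
  group's center is the mean position of its heavy members.
* **Ligand oxygen classes** — recovered from atom names so they survive a
  PDB round trip: sulfate oxygens → `SO4-`, carboxylate oxygens → `COO-`,
  ring oxygen → `O`, hydroxyl `O3`, glycosidic `O13`/`O14`, N-acetyl
  carbonyl `O7`, and the isomer-distinguishing sulfate ester oxygen
  (`O4S` in CS-4, `O6S` in CS-6). Anything else falls into `other`.

The receptor subdomain scheme is the HSA partition IA 5–107, IB 108–197,
IIA 198–296, IIB 297–382, IIIA 383–494, IIIB 495–569 (1-based, inclusive).
Residues 1–4 and 570–585 of the 585-residue chain map to `unassigned`;
they still participate in interaction detection but are reported
separately rather than folded into a neighboring subdomain. For reduced
fixtures the scheme is rescaled proportionally. Ligand mers group in
consecutive triples (24 mers → 8 groups; `ceil(mer/3)`).

On file input (multi-model PDB via biotite), bonds are perceived by
covalent-radius distances, restricted to same or adjacent residues so that
fixture atoms planted next to a foreign molecule never acquire spurious
bonds; each hydrogen keeps only its nearest heavy partner. Round-tripping
a generated system through PDB preserves names, partitions, coordinates to
the format's 3-decimal precision, and all derived annotations.

## Hydrogen-bond model

`hbond_energy(d_HA, θ_donor, θ_acceptor)` is a finite-range, angle-gated
model with an optimum of **25 kJ/mol**:

```
E = 25 kJ/mol × clamp((2.6 − max(d, 2.1)) / 0.5, 0, 1)
             × clamp((θ_d − 100°)/80°, 0, 1) × clamp((θ_a − 100°)/80°, 0, 1)
```

A bond is *counted* when E ≥ **6.25 kJ/mol**, i.e. 25% of the optimum. The
distance is H···acceptor; the donor angle is measured at the hydrogen
(D–H···A, 180° ideal); the acceptor angle is the angle between the
acceptor→H direction and the acceptor's mean covalent-bond direction
(180° when the hydrogen approaches anti to the acceptor's bonds, and 180°
by convention for acceptors with no heavy neighbor, e.g. water oxygen —
using the *mean* bond direction makes the definition single-valued for
multi-coordinated acceptors such as ring oxygens). Donors are N/O atoms
bearing hydrogens; acceptors are N/O atoms. Bifurcated geometries are
counted per donor–H···acceptor triple, not per atom pair. The ramp
constants (2.1 Å, 2.6 Å, 100°) are parameters of `AnalysisParams`, chosen
to reproduce the stated optimum and threshold with a conventional
hydrogen-bond reach; the threshold itself is derived as
`fraction × optimum` so the two can never drift apart.

## Distance criteria

Neither the hydrophobic nor the ionic criterion has a published value for
this system, so both are package defaults, config-exposed:

* `hp_cutoff` = **4.5 Å** between hydrophobic heavy atoms — common
  contact-analysis practice for apolar carbon pairs.
* `ionic_cutoff` = **5.0 Å** between charge-group centers — generous
  enough to cover a contact ion pair of a sulfate/carboxylate with a
  side-chain cation.

Bridges reuse these criteria unchanged: a **water bridge** is one water
molecule with a counted hydrogen bond to each solute in the same frame
(per-frame lifetime, no minimum duration — bridge populations are counted
per stored state); an **ionic bridge** is one cation within `ionic_cutoff`
of a negative receptor group center and a negative ligand group center
simultaneously. Anions never mediate. Bridge class labels join the
representative-atom elements around the mediator species (`C-Ca-C`,
`S-Ca-C`, `O-W-O`, …); individual ligand oxygens (ring/hydroxyl) can be
configured as coordination endpoints, yielding classes like `C-Ca-O`. The
same atom pair may appear in several censuses in one frame (HBo, HP and
ionic are independent counts), and one mediator may produce several bridge
records (one per endpoint pair).

## Windowed statistics

Every reported summary is the mean ± **doubled population STD** (ddof = 0)
over frames with `time > equilibration_time` and `time ≤ window_end`
(defaults 40 000 ps and 140 000 ps). The lower boundary is deliberately
strict: on the 1400-point save schedule exactly 1000 frames fall in the
window. An empty window raises `WindowError` rather than returning NaNs.
`equilibration_onset` defaults to returning the configured 40 ns; an
`auto` mode finds the first time from which the rolling-mean slope of the
RMSD series stays below a tolerance (default 10⁻³ Å/ps over a 10-frame
window) and falls back, with a warning, when no plateau exists.

## Superposition, RMSD, RMSF

Rigid superposition is the least-squares Kabsch solution via SVD with a
determinant correction, so the rotation is always proper (no reflection);
fewer than three atoms or a collinear selection raise `GeometryError`. The
default fit selection is the receptor backbone (N/CA/C/O) plus the ligand
ring and glycosidic atoms — "backbone" is not well defined for a sugar, so
the ring trace stands in and the selection is configurable. RMSD is
minimized over the fit selection; a separate measurement selection allows
closed-form checks (one atom displaced by d after fitting on the rest
gives d/√N exactly). RMSF is computed inside the analysis window after
superposing every frame on the receptor backbone (removing global
tumbling, about which the convention is otherwise silent), as the root of
the time-mean squared deviation from each atom's time-mean position.
Group aggregation *sums* member-atom RMSF per subdomain and per mer group,
so group values conserve the per-atom total; averaging over realizations
is a separate step over multiple trajectories, not hidden inside `rmsf`.

## Binding-energy accounting

The decomposition `E_bind = Epr + Epl + Esr + Esl − Epc − Esc` is an
accounting identity over ingested per-frame component energies (TSV); the
package deliberately does not recompute force-field potentials — the
components come from whatever engine produced the trajectory, and the
contribution here is the bookkeeping, windowing and ranking. EoB = −E_bind
is the reported, negative-favorable quantity. Solvation terms follow the
exposed-surface convention: SASA × **0.65 kJ/(mol·Å²)**. SASA is
Shrake–Rupley (biotite backend, 960 sphere points by default) with a fixed
radii table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, Na 2.27, Mg 1.73,
Ca 2.31, Cl 1.75 Å), override-able per call. Because the solvation cost
shifts EoB by a receptor-dependent constant, EoB is comparative only;
summaries always record the cost parameter used.

`rank_complexes` averages each complex's EoB means over its ionic
solutions, sorts ascending (most negative first, stable sort so ties keep
input order) and attaches docking ranks where provided (absent ranks are
reported as missing and never affect the order). The isomer contrast is
`100 × (|m₄| − |m₆|) / |m₄|` over the grand means of the per-complex EoB
columns — grand means over the ten per-complex values, not the thirty
per-solution values, which is the normalization that makes the reference
tables' contrast come out at ~15%. The reference ranking tables for the
ten CS-6 and ten CS-4 complexes (EoB mean ± STD, docking ranks, binding
sites) are packaged as module data and serve as fixed inputs to the
ranking and contrast logic.

## Contact maps and binding sites

Contact maps count in-window events per (ligand oxygen class × amino-acid
type) cell, for direct hydrogen bonds and for water bridges; counts, not
frequencies. Events whose ligand endpoint carries no class are tallied
under `other` and logged; ligand amide nitrogens count under `N`. Cell
totals equal the number of in-window events of that kind — a conservation
property the tests enforce against the census. Binding-site summaries
count direct-interaction events (HBo + HP + ionic; bridges excluded) per
receptor subdomain, list contacted subdomains hyphenated in canonical
order (IA < IB < IIA < IIB < IIIA < IIIB) and flag the argmax; ties flag
all maximal subdomains and log a warning. The strongest-site metric (event
count) is a package choice — an energy-weighted criterion would be equally
defensible — and is recorded in the report.

## Synthetic fixtures: what they emulate, and what they don't

The generator produces *kinematic* ground truth, not dynamics: no force
field, no integrator. It emulates the features the analysis code actually
consumes — composition (a multi-domain receptor of 585 residues at full
scale; an alternating GlcA/GalNAc 24-mer with one carboxylate per GlcA and
one sulfate per GalNAc; TIP-like water triplets; 2%-salt-scale ion counts
in a 120×110×110 Å box), annotation structure (oxygen classes, charge
groups, hydrophobic flags), a realistic save schedule, rigid-body solute
motion (≈2–3° rotations, 1.5–2 Å translations, smooth in time) and
per-atom Gaussian jitter. The receptor uses a reduced per-residue atom set
(backbone N/H/CA/C/O plus one side-chain pseudo-atom carrying the charge
group or polarity); the ligand geometry is idealized (fixed local
geometry, beads on a line) — downstream maps key on class labels, not
stereochemistry. Molecules are laid out in separated slabs so that,
outside planted frame ranges, no intermolecular contact satisfies any
detector criterion.

Planted events position the involved atoms (and mediator) to satisfy
their detector's criterion with ≥ 10% margin — hydrogen bonds at 2.0 Å
with ideal angles (full 25 kJ/mol), distance criteria at 80% of cutoff —
and simultaneous events are spaced so they cannot interfere (6 Å planar
gap between ionic-family sites, 5 Å otherwise, against maximal criterion
reaches of 5 Å and 4.6 Å). Event placement is validated at generation
time by running the real detectors on the pre-jitter geometry. Jitter is
applied after planting, so recovery degrades with jitter amplitude — by
design, and the tests verify the degradation is monotone over a seed
ensemble.

Passing on these fixtures establishes that the detectors implement their
stated geometric predicates exactly (they equal independent brute-force
all-pairs scans on every frame of randomized fixtures) and that the
pipeline's bookkeeping is correct. It does not establish anything about
real conformational ensembles: fixture geometry is idealized, solvent is
inert except where planted, and the toy component-energy tables used by
the pipeline's energetics stage are synthetic. Analyses of real
trajectories inherit only the criteria definitions, not any fixture
behavior.

## Numerical and scale choices

* Determinism: every stochastic element flows from a single integer seed
  through `numpy.random.default_rng`; identical configurations are
  bit-identical, and the pipeline writes a provenance log (seed,
  parameters, input hashes) alongside its outputs.
* Test problem sizes: the routine fixtures use the desk-scale
  configuration (60 receptor residues, 12-mer ligand, 500 waters — ≈2100
  atoms) or smaller; the oracle-equivalence suite runs twenty randomized
  200-frame fixtures of 600–900 atoms; the save-schedule check generates
  a minimal ~120-atom system over the full 1400-frame schedule. These
  sizes keep the whole validation chain at interactive latency while
  exercising every code path at full-scale composition ratios.
* Ties and degenerate inputs: ranking ties keep input order; binding-site
  ties flag all maximal subdomains; empty analysis windows, degenerate
  superposition selections, malformed PDB records (reported with line
  numbers), unknown residue names without a fallback partition, odd mer
  counts and infeasible box sizes all raise typed errors early.
* The "24 units" of the ligand chain are taken as 24 monosaccharide mers
  (12 disaccharide repeats) by default; the count is configurable, and
  the mer-group scheme adapts to any multiple of the group size.

## Known limitations

* Protonation states are not predicted; His is neutral unless flagged.
* The hydrogen-bond energy model is a documented reconstruction — optimum
  and threshold are fixed by the stated values, but the ramp shape between
  them is a package choice (configurable constants).
* Component potential energies are never computed from coordinates; the
  energetics stage is only as meaningful as the ingested tables.
* No π-stacking, cation–π or halogen-bond detection; no two-water bridge
  chains or mixed cation+water bridges; no secondary-structure analysis.
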