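# Methods

## Scope and model

ncidyn analyzes existing MD trajectories; it does not run simulations. Its unit
of analysis is the *unique contact*: a typed, atom-level interaction identity —
(negative O, positive N) for a salt bridge, (donor, hydrogen, acceptor) for a
hydrogen bond, an unordered carbon pair for a hydrophobic contact — together
with the boolean vector of frames in which its geometric criterion holds.
Occupancy percentages, lifetime classes, decile histograms, per-frame mean
counts, category decompositions and two-condition difference tables are all
derived from these presence vectors, never from rounded intermediate reports.

## Geometric criteria and their edges

| quantity | criterion | default |
|---|---|---|
| salt bridge | d(O⁻, N⁺) ≤ cutoff | 0.4 nm |
| hydrogen bond | d(D, A) ≤ cutoff and ∠(D–H–A) ≥ minimum | 0.35 nm, 120° |
| hydrophobic | d(C, C) ≤ cutoff, residues ≥ `min_res_separation` apart | 0.4 nm, 1 |

All cutoffs are inclusive. Comparisons carry a 1e-9 guard so a pair constructed
exactly at a boundary is classified deterministically: 0.35 nm at 120.0° is a
hydrogen bond; 0.351 nm or 119.9° is not. The hydrophobic cutoff is exposed
because a 0.39 nm criterion also circulates in the literature; 0.4 nm is the
default. Intra-residue donor–acceptor pairs are excluded (their geometry is
fixed by covalent structure); sequence-adjacent residues are retained because
backbone i→i+4 bonds are the substance of the mainchain–mainchain category.
`min_res_separation = 1` excludes only same-residue carbon pairs, which would
otherwise dominate the counts at bond distances.

Hydrogen-bond donors are N/O atoms with ≥ 1 attached hydrogen and acceptors are
all N/O atoms of protein and water, the convention of the common
trajectory-analysis tools. When the input carries no bond records, hydrogens
are attached to the nearest N/O within 0.12 nm in the reference frame. His is
included in hydrogen-bond accounting but excluded from salt-bridge participant
sets, and its residue class is OTHER (it belongs to none of the three standard
class lists); consequently it counts in SASA totals but in neither the
hydrophobic nor the hydrophilic bucket, and His-mediated hydrogen bonds appear
in IP/MM/MS/SS but in no residue-class category. "Terminal groups" are read
narrowly for the salt-bridge exclusion: the backbone carboxylate (C/O/OXT) of a
chain's last residue and the backbone ammonium (N + hydrogens) of its first; a
terminal Glu's sidechain carboxylate remains eligible.

Candidate pairs come from a KD-tree (periodic when the minimum-image option is
on); the test suite holds every detector to exact set equality with an
all-pairs brute-force oracle, so the acceleration is an implementation detail.
Minimum-image is off by default: whole-molecule trajectories do not need it,
and applying it to a dimer would double-count interface contacts through the
box walls.

## Lifetime statistics

Occupancy bins are half-open on the left, (a, b]: exactly 10 % is short-lived,
exactly 90 % is substantially lived, exactly 100 % long-lived. The occupancy
filters used in difference tables ("drop contacts existing ≤ 5 % / ≤ 10 % of
the time") likewise remove the boundary value itself. A 1e-9 tolerance at bin
edges protects ratios that are exact in decimal but not in binary after stride
arithmetic. Two summaries can only be differenced when computed with identical
detector parameters; a mismatch raises rather than warns.

## Structural metrics

Superposition is the Kabsch SVD solution constrained to proper rotations
(det = +1), cross-checked in tests against MDAnalysis. RMSD/RMSF are computed
over Cα atoms, superposed by default (a `fit=False` path exists for closed-form
tests and pre-aligned trajectories), and reported in Å while SASA is reported
in nm² — the mixed unit convention of the tables this package mirrors. RMSF
supports the initial structure or the time-mean structure as reference. The
Cα–Cα matrix is time-averaged over the analysis window because condition
differencing requires a window aggregate; a single-frame matrix is just a
one-frame window. Difference matrices flag residue pairs whose mean distance
changed by ≥ 1 nm (configurable), reported once per unordered pair.

SASA is Shrake–Rupley with Bondi radii (C 0.170, N 0.155, O 0.152, S 0.180,
H 0.120 nm), probe 0.14 nm, and a 960-point Fibonacci sphere per atom; water is
excluded both as surface and as occluder. 960 points put the isolated-sphere
error near 1e-3 relative and converge within 1 % of a 4000-point run on toy
systems; both knobs are exposed.

## Synthetic data: what it emulates and what it does not

The generator builds protein-like topologies (standard PDB atom naming, correct
donor hydrogens, one residue of every class plus His, waters appended) with
residues on a wide grid so that the home configuration contains *zero*
contacts. A contact schedule then teleports one mobile atom per contact into
exact on-geometry in its scheduled frames and to a far-off position otherwise.
Key invariants, enforced at generation time:

- Per-atom positional noise is bounded by 0.02 nm — strictly below half the
  0.05 nm margin separating on/off geometry from every criterion — and mobile
  atoms are placed exactly relative to their *noisy* anchors, so detector
  outcomes are noise-invariant and ground truth is exact, not statistical.
- Mobile atoms travel without their hydrogens, so a displaced donor can never
  form an unscheduled hydrogen bond (its hydrogen is ~1 nm away, making the
  D–H–A angle collapse); an acceptor that itself carries hydrogens is rejected
  as a schedule target for the symmetric reason.
- Approach directions are chosen by inverse-cube repulsion from neighboring
  atoms, and nominal on/off placements are checked against every atom a
  detector could pair them with; crowded anchors (e.g. aromatic ring carbons
  with neighbors on both sides) are rejected with an explanatory error.
- Every generated frame is verified to contain exactly the scheduled contacts.

Target occupancies are realized as ⌊round(p·N/100)⌋ frames spread evenly over
the window, and the manifest records the realized (exact) percentage. The
generator's defaults — 2 ps frame spacing, 200-frame example windows, 0.02 nm
jitter — define the study conditions of the example thermal pair, which places
contacts exactly on the 5 %, 10 % and 90 % boundaries and encodes the
qualitative signature of a stabilized mutant at elevated temperature (gained
unique salt bridge and hydrophobic contact, lost water hydrogen bond,
long-lived contacts shifted to shorter classes).

What passing these tests shows: the bookkeeping — detection, uniqueness,
occupancy arithmetic, classification, category partitions, differencing — is
exact. What it does not show: anything about real conformational dynamics.
Synthetic trajectories have no physical forces, no correlated motion, no
diffusing water, and contact on/off transitions are instantaneous; real
trajectories sample geometry continuously across the cutoffs, where results
depend on the criteria themselves.

## Numerical and design choices

- Internal units are nm/ps everywhere; PDB Å is converted at the I/O boundary.
  This keeps the 0.35/0.4 nm cutoffs literal in code.
- Analysis windows are inclusive on both ends ("10 ns to 40 ns" keeps both
  endpoint frames); stride keeps every k-th surviving frame.
- Registries are kind-homogeneous (SB/HB/HP held separately); cross-kind totals
  exist only at report level.
- Mixed-class hydrogen bonds (e.g. polar–charged) count in IP and its role
  categories but in no class category; no "mixed" bucket is invented. Bonds
  with exactly one water partner are water-category only and excluded from IP;
  water–water bonds are counted in no category.
- Report CSVs are deterministically ordered and byte-identical across reruns.
- The crystal-structure comparison (`crystal_ca_rmsd`) matches chains by order
  and residues by sequence number, superposes the common Cα set, and reports Å;
  it requires the user to supply the PDB files.

## Problem sizes

The shipped example study uses a 14-residue + 3-water topology (~170 atoms) and
200-frame windows; detector oracle checks run on 20 dense random frames of the
same topology. These sizes keep the full suite and the acceptance script in the
seconds range while exercising every code path; all operations scale to real
systems (the detectors are O(N log N) per frame via KD-trees, SASA O(N·k) in
neighbor count).

## Known limitations

- Orthorhombic boxes only; no re-imaging of molecules broken across boundaries.
- No protonation-state prediction; donors are read off the file's hydrogens.
- Occupancy is the only lifetime measure — no residence-time autocorrelation
  or kinetic modelling.
- π–π and cation–π interactions, secondary-structure assignment and radius of
  gyration are out of scope.
- Alternate locations beyond highest-occupancy and non-standard residues are
  not handled (unknown residues classify as OTHER).
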