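# ncidyn

Dynamic analysis of non-covalent interactions (NCIs) in protein molecular-dynamics
trajectories: salt bridges, hydrogen bonds and hydrophobic contacts detected frame
by frame with geometric criteria, aggregated into unique-contact occupancy
statistics, and compared between two simulation conditions (wild-type vs mutant,
or two temperatures). It also computes the standard structural metrics used
alongside such comparisons: Cα RMSD and RMSF, time-averaged Cα–Cα distance maps
with condition differencing, and Shrake–Rupley solvent-accessible surface area
(SASA) split into hydrophobic and hydrophilic residue totals.

The intended user is a structural bioinformatician asking how a protein's contact
network reorganizes between conditions — for example, why a thermostable point
mutant of a dimeric enzyme keeps its fold at elevated temperature while the wild
type does not. The answer such studies give is phrased in terms of how many
unique contacts exist, how long each lives, and how those counts shift with
temperature; this package computes exactly those tables.

## Definitions

For a trajectory window of `N` frames (default 10–40 ns at 2 ps spacing):

- **Salt bridge** — a carboxylate oxygen of Asp (Oδ1/Oδ2) or Glu (Oε1/Oε2)
  within **0.4 nm** of a charged nitrogen of Arg (Nε/Nη1/Nη2) or Lys (Nζ).
  Histidine and the backbone carboxylate/ammonium groups of chain termini are
  excluded.
- **Hydrogen bond** — donor–acceptor distance **≤ 0.35 nm** and
  donor–hydrogen–acceptor angle **≥ 120°** (both inclusive). Donors are N/O
  atoms with an attached hydrogen; acceptors are all N/O atoms. The same
  donor–acceptor pair bonded through a different hydrogen is a distinct contact.
- **Hydrophobic contact** — two carbons from the standard hydrophobic-atom name
  set (C, Cα, Cβ, Cγ…, Cη2) in different residues within **0.4 nm**, each
  unordered pair counted once.
- **Occupancy** (existence percentage) of a unique contact:
  `X = 100 · (frames present) / N`. Contacts are classified
  **short-lived** (0 < X ≤ 10), **substantially lived** (10 < X ≤ 90) and
  **long-lived** (90 < X ≤ 100), and binned into ten 10 % occupancy deciles.
- **Time-averaged count** — mean number of contacts per frame.
- Hydrogen bonds are decomposed into intra-protein (IP) bonds by donor/acceptor
  role — mainchain–mainchain (MM), mainchain–sidechain (MS), sidechain–sidechain
  (SS), with MM + MS + SS = IP — and by residue class (PP, CC, HH for
  polar/charged/hydrophobic pairs); bonds with exactly one water partner are
  bucketed as protein–water (mainchain/sidechain and by residue class).
- A **condition difference** is the elementwise subtraction (B − A) of all of
  the above, computed from the registries after applying the same occupancy
  filter (e.g. drop contacts with X ≤ 5 %) to both sides.

Residue classes follow the standard lists: charged = {Arg, Lys, Asp, Glu},
polar = {Gln, Asn, Ser, Thr, Tyr, Cys}, hydrophobic = {Ala, Ile, Leu, Phe, Val,
Pro, Gly, Met, Trp}; His belongs to none of them.

## Worked example

The synthetic-data module generates toy systems whose contact schedule — which
contacts exist, in which frames, at what geometry — is known exactly, so every
statistic the pipeline reports can be checked against the generator's manifest.
`example_thermal_pair_specs` builds a canned two-condition study ("cold" vs
"hot") over a 14-residue topology with three waters:

```python
from ncidyn.synthetic_data import example_thermal_pair_specs, make_condition_pair
from ncidyn import summarize_condition, condition_difference

spec_cold, spec_hot = example_thermal_pair_specs(n_frames=200, seed=1)
(traj_cold, truth_cold), (traj_hot, truth_hot) = make_condition_pair(spec_cold, spec_hot)

cold = summarize_condition(traj_cold, "cold")
hot = summarize_condition(traj_hot, "hot")
print("unique cold:", cold.unique_counts())
print("unique hot: ", hot.unique_counts())

diff = condition_difference(cold, hot)          # hot - cold
print("d_unique:", diff.unique)
print("d_time_averaged:", {k: round(v, 2) for k, v in diff.time_averaged.items()})
print("d_lifetime SB:", diff.lifetime["SB"])
```

prints

```
unique cold: {'SB': 3, 'HB': 9, 'HP': 4}
unique hot:  {'SB': 4, 'HB': 8, 'HP': 5}
d_unique: {'SB': 1, 'HB': -1, 'HP': 1}
d_time_averaged: {'SB': -0.82, 'HB': -0.62, 'HP': 0.42}
d_lifetime SB: {'short': 1, 'substantial': 2, 'long': -2}
```

Reading: the hot condition gained one unique salt bridge and one unique
hydrophobic contact and lost one hydrogen bond (a water bond); its salt bridges
shifted from long-lived (−2) toward substantial (+2) and short-lived (+1)
occupancy, and the mean per-frame salt-bridge count dropped by 0.82. Every one
of these numbers equals the generator's scheduled ground truth.

For file-based workflows the same analysis runs from the shell:

```bash
ncidyn compare --cond cold=top.pdb,cold.xtc --cond hot=top.pdb,hot.xtc \
    --begin-ps 10000 --end-ps 40000 --filter-le 5 --out report/
```

which writes per-condition summary, category, decile and registry CSVs plus the
difference tables.

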