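# Methods

This note documents the models implemented in `interlock`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that make results reproducible.

## Co-evolution by mutual information

For small alignments (on the order of 100 sequences), mutual information
with pseudocount regularisation is the appropriate co-evolution statistic;
direct-coupling methods need far more sequences. The pipeline is:

1. **Gap filter.** Columns whose gap fraction strictly exceeds
   `max_gap_fraction` (default 0.30) are removed per domain; `X` counts as a
   gap. A column at exactly the threshold is retained. A column map back to
   original 1-based numbering is kept so reported pairs use input
   coordinates.
2. **Concatenation.** The two per-domain alignments are joined row-wise;
   they must share the same ordered identifiers (no silent reordering). The
   domain boundary classifies pairs as `intra_A`, `intra_B` or `inter`.
3. **Joint estimation.** For each column pair, P_obs comes from rows
   ungapped at both columns; the pseudocount mixes in the product of column
   profiles with weight τ = (1+b)/(e^{a·Neff}+b). Neff is by default the
   plain count of rows ungapped at both columns; an optional weighted mode
   down-weights near-duplicate rows by 1/cluster-size at a configurable
   identity threshold (default 0.8), since whether redundancy weighting
   belongs inside Neff is a judgement call — both modes are provided.
4. **MI and APC.** MI is computed in nats on the pseudocounted joint, with
   marginals taken as row/column sums of that joint (so MI is evaluated on a
   proper distribution; terms with zero joint probability contribute
   nothing). The average-product correction subtracts
   MI(i,·)MI(·,j)/MI(·,·), with averages over off-diagonal entries; a zero
   overall average means no correction is possible and MI is returned
   unchanged.
5. **Ranking.** Descending by MIp, ties broken by MI (descending) then by
   (i, j) — fully deterministic. Intra-domain pairs closer than
   `min_separation` (default 5) columns are excluded: chain neighbours carry
   trivial covariation that would otherwise flood the top ranks. An `mi`
   ranking mode exists for comparison.

**Constants.** The pseudocount constants are a = 0.05, b = 10 by default:
τ ≈ 1 below a handful of effective sequences and τ < 0.1 by Neff ≈ 90, i.e.
the prior dominates only when data are scarce. These are package defaults,
exposed in the config; no claim is made that they match any particular
legacy tool's internal constants. Log base is natural; any other base
rescales all scores identically and cannot change ranks.

## Protein structure networks

Nodes are residues. The interaction strength between residues i and j is
I(i,j) = 100 · n_ij / √(N_i N_j), with n_ij the number of heavy-atom pairs
(one atom from each residue) within `contact_cutoff` (default 4.5 Å) and
N_i a per-residue-type normalization constant. The shipped table uses
literature-style magnitudes (≈47 for Gly up to ≈107 for Trp) and is fully
editable — the normalization is a convention, and any consistent table
yields the same network topology up to a rescaling of I_min. Intra-chain
pairs within `exclude_neighbors` (default 2) in sequence are dropped so
covalent neighbours cannot provide trivial backbone paths.

**I_min selection.** The size of the largest connected cluster is profiled
over an I_min grid (default 0 to 10 % in 0.5 % steps). The selected I_min is
the grid value at which the drop from the previous point is maximal (first
on ties); a constant profile yields a no-transition flag and callers fall
back to 2.5, the conventional default. Sizes are guaranteed non-increasing
along the grid.

**Dynamic stability.** An edge is dynamically stable when present in at
least the `stability` fraction of frames (default 0.5, inclusive — "at
least half the trajectory" is the natural reading). Stable-edge strength is
averaged over the frames where the edge exists.

**Paths.** Shortest paths minimise hop counts (the path with the least
residues); a strength-weighted mode (edge length 1/strength) exists behind
a flag. All-pairs distances come from a vectorised Floyd–Warshall; the
reported path is reconstructed greedily on the distance field, taking at
each step the smallest residue key that stays on a shortest path, which
makes tie-breaking deterministic (lexicographically smallest node sequence).
Ensemble analysis computes the path in every frame, averages hop counts over
frames that have a path, reports residues present in at least
`consensus_fraction` (default 0.5) of per-frame paths, and also reports the
path on the stable network — whether per-frame or stable-network paths are
the more faithful summary is context-dependent, so both are emitted.
Residues of either chain may appear as intermediates; chain membership is
visible in the node labels.

## Interface characterisation

* **Interface residues:** any residue with a heavy atom within
  `interface_cutoff` (default 5.0 Å) of the other chain. Symmetric in the
  chains.
* **Hydrogen bonds:** donor–acceptor heavy-atom distance ≤ 3.5 Å, with
  standard N/O donor/acceptor roles per residue type (backbone N donates
  except proline, backbone O accepts, plus the usual side-chain table).
  When explicit hydrogens are present a hydrogen–donor–acceptor angle
  ≤ 30° is additionally required; heavy-atom-only ensembles are judged on
  distance alone. Occupancy is the fraction of frames a residue pair is
  bonded; **stable means occupancy strictly greater than 0.5** — a bond
  present in exactly half the frames is not stable.
* **Pseudoenergies:** additive per-interaction increments at distance
  thresholds — e_hb = −1.5 kcal/mol per cross-chain H-bond, ±1.0 kcal/mol
  per charged-group pair within 6.0 Å (attractive for opposite formal
  charges: Asp/Glu −1, Lys/Arg +1, His neutral), −0.2 kcal/mol per
  heavy-atom pair in [3.0, 5.0] Å. These constants are **calibrated
  stand-ins, not physics**: they make totals comparable across frames and
  complexes and put a tight toy interface in the few-kcal/mol-per-residue
  regime, but they are not binding free energies. Every constant is
  configurable.
* **Attribution and hotspots:** each pairwise term is split equally between
  its two residues, so per-residue energies sum exactly to the total
  (conservation is asserted in tests to 1e-6). A hotspot is an interface
  residue whose attributed energy is at or below `hotspot_threshold`
  (default −2.0 kcal/mol).

## Ensemble metrics

Backbone means N, CA, C, O. RMSD uses Kabsch superposition (SVD with
determinant correction) fitted on the selection and applied to all atoms.
Rg is mass-weighted by default. RMSF is computed on Cα over a trailing
window (default the last 20 % of frames, configurable as a fraction or an
explicit frame range), after superposing each window frame onto an
iteratively refined mean structure; two refinement passes are used — the
procedure is deterministic and converged at the problem sizes here.

## Synthetic data: what it emulates and what it does not

`generate_coupled_msa` draws per-column profiles from a symmetric Dirichlet
(concentration 1.0 by default), samples rows i.i.d., overwrites planted
column pairs through a fixed alphabet bijection with probability =
`strength`, and sprinkles gaps i.i.d. It emulates *column-wise covariation
against a profile background* — it does **not** emulate phylogenetic
correlation between rows, which in real alignments is the dominant
confounder that APC only partially removes. Passing the planted-pair
benchmark therefore shows the statistic and its correction are implemented
correctly, not that 100 sequences suffice for reliable contact prediction
in real families.

`generate_toy_complex` builds two non-self-intersecting Cα traces (3.8 Å
steps) with 1–3 pseudo side-chain atoms per residue: designated cross-chain
contact pairs reach within 4.5 Å (hydrogen-bond pairs get an N/O pair at
3.0 Å), all other cross-chain residue pairs stay ≥ 8 Å apart, and the
planted path residues form a 4.2 Å-spaced contact chain with intervening
residues routed over circular arcs. Feasibility requires contact and path
residues to be ≥ 3 apart in sequence (closer path pairs would be discarded
as covalent neighbours; closer contacts cannot keep non-contact pairs at
8 Å). Every guarantee is re-verified after placement by a brute-force scan;
a few alternative arc orientations are tried before raising a geometry
error. Because pseudo-residues carry ~3 heavy atoms versus ~8 in real
residues, interaction strengths are proportionally lower: toy-complex
analyses (demo config, tests) use I_min = 1.0, while the package default
for real structures remains 2.5.

`generate_ensemble` adds i.i.d. isotropic Gaussian displacement per atom —
geometric variability with known ground truth, not physical dynamics (no
correlated motions, no solvent, no barostat artefacts). A
`broken_fraction` of frames has the partner chain rigidly translated 20 Å
along the interface normal, as a contiguous trailing block by default
(mimicking a dissociation event and exercising time-blocked disruption); a
`scattered` flag distributes them randomly instead. All generators are
bit-reproducible from their seed.

## Problem sizes and determinism

The bundled demo and the acceptance script use 100-sequence alignments of
25+25 columns, a 50-residue two-chain complex, and 5–10-frame ensembles —
sizes at which every stage completes in seconds while still exercising all
code paths; statistical checks (planted-pair recovery, MI monotonicity in
coupling strength) aggregate over 20 seeds. Floyd–Warshall is O(n³) in the
node count and comfortable for single-domain networks (hundreds of
residues); for much larger systems a per-source BFS would be the right
substitution. All randomness flows through `numpy.random.default_rng`
seeds; TSV outputs use fixed 6-decimal formatting, so identical config and
seed give byte-identical files.

## Known limitations

* The co-evolution module implements MI/MIp only; no phylogeny-aware or
  direct-coupling corrections beyond the pseudocount/APC scheme. A further
  "MIc" variant seen in some legacy tool outputs has no published
  definition and is deliberately not implemented.
* Pseudoenergies are threshold counts; no solvation, polarisation or
  buried-surface-area terms.
* PDB input only (one thin format; mmCIF or compressed trajectories should
  be converted externally, e.g. to multi-model PDB). HETATM records are
  ignored; alternate locations resolve to the highest-occupancy conformer.
* The toy-complex planner handles the blueprint geometries described above;
  wildly interleaved path/contact layouts can be rejected with a geometry
  error rather than silently mis-built.
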